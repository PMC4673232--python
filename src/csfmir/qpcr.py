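"""RT-PCR relative quantification (2^-ddCt) and the comparison battery.

Pipeline, mirroring standard TaqMan practice: technical triplicates are
collapsed by arithmetic mean; a mean Ct at or above the undetected threshold
(default 39 cycles, "close or equal to 40") marks the miRNA as not expressed
in that sample; dCt is taken against the cel-miR-248 spike-in; patients with
longitudinal samples contribute the mean dCt over their time points; group
comparisons report ddCt = mean dCt(up) - mean dCt(ref), the fold change
2^-ddCt, and a one-tailed Welch t-test (alternative: the hypothesized
up-regulated group has lower dCt).  Undetected values are excluded from
means; a group entirely undetected yields a "(not expressed)" annotation
instead of a finite fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import CohortDesign
from .effects import ComparisonRow, SPIKE_IN, PUBLISHED_COMPARISONS, resolve_group

DEFAULT_UNDETECTED_THRESHOLD = 39.0
P_FLOOR = 1e-300


@dataclass(frozen=True)
class ComparisonResult:
    mirna: str
    up_group: str
    ref_group: str
    n_up: int
    n_ref: int
    ddct: float
    fold_change: float
    p_value: float
    annotation: str = ""
    error: str = ""

    def as_dict(self) -> dict:
        return {
            "mirna": self.mirna, "up_group": self.up_group,
            "ref_group": self.ref_group, "n_up": self.n_up, "n_ref": self.n_ref,
            "ddct": self.ddct, "fold_change": self.fold_change,
            "p_value": self.p_value, "annotation": self.annotation,
            "error": self.error,
        }


def collapse_triplicates(ct: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (sample, miRNA) with the replicate count recorded."""
    grouped = ct.groupby(
        ["sample_id", "patient_id", "group", "mirna"], sort=False
    )["ct"]
    out = grouped.agg(mean_ct="mean", n_replicates="count").reset_index()
    return out


def flag_not_expressed(mean_ct, threshold: float = DEFAULT_UNDETECTED_THRESHOLD):
    """Detected flag: True iff mean Ct < threshold.

    The boundary itself counts as undetected (a Ct of exactly ``threshold``
    is "close to 40").
    """
    return np.asarray(mean_ct) < threshold


def compute_delta_ct(
    mean_ct: pd.DataFrame,
    spike_in_id: str = SPIKE_IN,
    threshold: float = DEFAULT_UNDETECTED_THRESHOLD,
) -> pd.DataFrame:
    """Per-(sample, miRNA) dCt vs the spike-in and 2^-dCt relative expression.

    Samples whose spike-in is undetected fail QC and are dropped (with a
    ``qc_failed_samples`` attribute on the result).  Undetected target
    miRNAs keep their censored dCt but are flagged ``detected=False`` and are
    excluded from group means downstream.
    """
    spike = mean_ct[mean_ct["mirna"] == spike_in_id]
    if spike.empty:
        raise ValueError(f"spike-in {spike_in_id!r} absent from dataset")
    spike_map = spike.set_index("sample_id")["mean_ct"]
    bad = sorted(spike_map.index[~flag_not_expressed(spike_map, threshold)])

    targets = mean_ct[mean_ct["mirna"] != spike_in_id].copy()
    known = targets["sample_id"].isin(spike_map.index)
    if not known.all():
        raise ValueError("samples without spike-in records: "
                         f"{sorted(targets.loc[~known, 'sample_id'].unique())}")
    targets = targets[~targets["sample_id"].isin(bad)].copy()
    targets["delta_ct"] = (
        targets["mean_ct"].to_numpy()
        - spike_map.loc[targets["sample_id"]].to_numpy()
    )
    targets["detected"] = flag_not_expressed(targets["mean_ct"], threshold)
    targets["rel_expr"] = 2.0 ** (-targets["delta_ct"])
    targets.attrs["qc_failed_samples"] = bad
    return targets.reset_index(drop=True)


def average_patient_timepoints(profiles: pd.DataFrame) -> pd.DataFrame:
    """Mean dCt per (patient, miRNA) over that patient's detected samples.

    A patient with no detected sample for a miRNA is kept with
    ``detected=False`` (dCt = mean of the censored values) so absence can be
    reported rather than silently dropped.
    """
    def agg(sub: pd.DataFrame) -> pd.Series:
        det = sub[sub["detected"]]
        used = det if len(det) else sub
        return pd.Series({
            "delta_ct": used["delta_ct"].mean(),
            "detected": bool(len(det)),
            "n_samples": int(len(used)),
        })

    out = (
        profiles.groupby(["patient_id", "group", "mirna"], sort=False)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    out["rel_expr"] = 2.0 ** (-out["delta_ct"])
    return out


def fold_change_ddct(up_dcts, ref_dcts) -> tuple[float, float]:
    """ddCt = mean(up) - mean(ref); FC = 2^-ddCt (>1 means up-regulated)."""
    up = np.asarray(up_dcts, dtype=float)
    ref = np.asarray(ref_dcts, dtype=float)
    if len(up) == 0 or len(ref) == 0:
        raise ValueError("need >= 1 detected patient per group")
    ddct = float(up.mean() - ref.mean())
    return ddct, float(2.0 ** (-ddct))


def one_tailed_t_test(up_dcts, ref_dcts, welch: bool = True,
                      two_tailed: bool = False) -> float:
    """Welch (default) t-test that the up group has *lower* dCt.

    Returns p in (0, 1].  Degenerate zero-variance input: equal means give
    p = 0.5 (one-tailed symmetric null); separated means give the numerical
    floor.
    """
    up = np.asarray(up_dcts, dtype=float)
    ref = np.asarray(ref_dcts, dtype=float)
    if len(up) < 2 or len(ref) < 2:
        raise ValueError("need n >= 2 detected patients per group for a t-test")
    if up.var(ddof=1) < 1e-20 and ref.var(ddof=1) < 1e-20:
        if up.mean() == ref.mean():
            return 0.5 if not two_tailed else 1.0
        if two_tailed:
            return P_FLOOR
        return P_FLOOR if up.mean() < ref.mean() else 1.0 - P_FLOOR
    alternative = "two-sided" if two_tailed else "less"
    res = stats.ttest_ind(up, ref, equal_var=not welch, alternative=alternative)
    return float(max(res.pvalue, P_FLOOR))


def run_comparison_battery(
    patient_profiles: pd.DataFrame,
    design: CohortDesign,
    specs: tuple[ComparisonRow, ...] = PUBLISHED_COMPARISONS,
    welch: bool = True,
    two_tailed: bool = False,
) -> pd.DataFrame:
    """One result row per comparison spec; errors are per-row, not fatal.

    A comparison whose reference (or up) group is entirely undetected for the
    miRNA is annotated "(not expressed)" with no finite fold change,
    mirroring the printed table's miR-935 rows.
    """
    results = []
    for spec in specs:
        try:
            results.append(
                _run_one(patient_profiles, design, spec, welch, two_tailed)
            )
        except (KeyError, ValueError) as exc:
            results.append(ComparisonResult(
                spec.mirna, spec.up_group, spec.ref_group, 0, 0,
                math.nan, math.nan, math.nan, error=str(exc)))
    return pd.DataFrame([r.as_dict() for r in results])


def _group_profile(profiles: pd.DataFrame, design: CohortDesign,
                   mirna: str, label: str, other: str | None) -> pd.DataFrame:
    ids = resolve_group(label, design, other=other)
    sub = profiles[(profiles["mirna"] == mirna)
                   & profiles["patient_id"].isin(ids)]
    return sub


def _run_one(profiles, design, spec: ComparisonRow, welch, two_tailed):
    if spec.up_group == spec.ref_group:
        raise ValueError("comparison between a group and itself is undefined")
    up = _group_profile(profiles, design, spec.mirna, spec.up_group,
                        other=spec.ref_group)
    ref = _group_profile(profiles, design, spec.mirna, spec.ref_group,
                         other=spec.up_group)
    up_det = up[up["detected"]]
    ref_det = ref[ref["detected"]]

    if len(ref_det) == 0 or len(up_det) == 0:
        side = spec.ref_group if len(ref_det) == 0 else spec.up_group
        return ComparisonResult(
            spec.mirna, spec.up_group, spec.ref_group,
            len(up_det), len(ref_det), math.nan, math.nan, math.nan,
            annotation=f"{side} (not expressed)")

    ddct, fc = fold_change_ddct(up_det["delta_ct"], ref_det["delta_ct"])
    if len(up_det) >= 2 and len(ref_det) >= 2:
        p = one_tailed_t_test(up_det["delta_ct"], ref_det["delta_ct"],
                              welch=welch, two_tailed=two_tailed)
        err = ""
    else:
        p, err = math.nan, "p undefined: fewer than 2 detected patients in a group"
    return ComparisonResult(spec.mirna, spec.up_group, spec.ref_group,
                            len(up_det), len(ref_det), ddct, fc, p,
                            error=err)


def quantify(ct: pd.DataFrame,
             threshold: float = DEFAULT_UNDETECTED_THRESHOLD) -> pd.DataFrame:
    """Full sample->patient pipeline: collapse, dCt, time-point averaging."""
    return average_patient_timepoints(
        compute_delta_ct(collapse_triplicates(ct), threshold=threshold)
    )
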