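"""Executable CSF diagnostic chart for CNS tumors.

The chart classifies a patient's five-miRNA CSF profile (miR-451, -711,
-935, -223, -125b, each a 2^-dCt relative expression plus a detected flag)
by first binning each miRNA into one of four ordinal categories — absent,
low, moderate, high — and then walking a fixed first-match-wins rule
cascade:

  R1  miR-451 low, miR-711 moderate, miR-935 moderate/high  -> Normal
  R2  miR-451 moderate/high, miR-711 moderate, miR-935 moderate -> Benign
  R3  miR-935 absent, miR-711 low                            -> Lymphoma
  R4  miR-935 absent, miR-711 moderate/high -> Glioblastoma vs
      Medulloblastoma by the second tier: miR-223 high and above miR-125b
      -> Glioblastoma; miR-125b high and above miR-223 -> Medulloblastoma;
      neither dominant -> Indeterminate
  R5  miR-935 high, miR-223 moderate/high, miR-125b moderate/high ->
      Metastasis; miR-935 at/above the lung/breast sub-boundary -> lung,
      below -> breast

R3 precedes R4 because both require absent miR-935 and R3 is stricter.
Indeterminate is a first-class outcome: the chart abstains rather than
forcing a nearest class.

The chart itself states only *relative* levels, so the numeric category
boundaries are calibrated from a labeled reference cohort: per miRNA, group
means of log2 relative expression are computed, each group is assigned its
chart level (the module-level ``CHART_LEVELS`` template transcribes the
chart's qualitative wording), and each boundary is the log2 midpoint between
the highest mean of the lower level and the lowest mean of the upper level.
An unsupervised variant ("gap": boundaries at the two largest inter-group
gaps) is available for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import TARGET_MIRNAS

CATEGORIES = ("absent", "low", "moderate", "high")
_ORD = {c: i for i, c in enumerate(CATEGORIES)}

CALL_LABELS = (
    "Normal", "Benign", "Lymphoma", "Glioblastoma", "Medulloblastoma",
    "Metastasis-Lung", "Metastasis-Breast", "Indeterminate",
)

#: Chart level of each cohort group per miRNA ("absent" = undetected).
CHART_LEVELS: dict[str, dict[str, str]] = {
    "miR-451": {"Normal": "low", "Lymphoma": "low", "Medulloblastoma": "moderate",
                "Benign": "high", "Glioblastoma": "high",
                "LungMetastasis": "high", "BreastMetastasis": "high"},
    "miR-711": {"Lymphoma": "low", "Normal": "moderate", "Benign": "moderate",
                "LungMetastasis": "moderate", "BreastMetastasis": "moderate",
                "Glioblastoma": "high", "Medulloblastoma": "high"},
    "miR-935": {"Glioblastoma": "absent", "Medulloblastoma": "absent",
                "Lymphoma": "absent", "Normal": "moderate", "Benign": "moderate",
                "LungMetastasis": "high", "BreastMetastasis": "high"},
    "miR-223": {"Normal": "low", "Lymphoma": "low", "Benign": "moderate",
                "Medulloblastoma": "moderate", "LungMetastasis": "moderate",
                "BreastMetastasis": "moderate", "Glioblastoma": "high"},
    "miR-125b": {"Normal": "low", "Benign": "moderate", "Lymphoma": "moderate",
                 "Glioblastoma": "moderate", "LungMetastasis": "moderate",
                 "BreastMetastasis": "moderate", "Medulloblastoma": "high"},
}

#: Expected diagnosis per cohort group (metastases map to their subtype call).
GROUP_TO_CALL = {
    "Normal": "Normal", "Benign": "Benign", "Lymphoma": "Lymphoma",
    "Glioblastoma": "Glioblastoma", "Medulloblastoma": "Medulloblastoma",
    "LungMetastasis": "Metastasis-Lung", "BreastMetastasis": "Metastasis-Breast",
}

#: Margin (log2 units) used for a boundary adjoining an empty level.
EMPTY_LEVEL_MARGIN = 2.0


@dataclass
class CategoryThresholds:
    """Per-miRNA (low|moderate, moderate|high) boundaries, log2 rel-expr scale.

    A miRNA undetected in every calibrating group is threshold-free
    (absent/present only, boundaries None).  ``metastasis_subboundary`` is
    the log2 miR-935 cut separating lung from breast metastasis.
    """

    boundaries: dict[str, tuple[float, float] | None]
    metastasis_subboundary: float | None = None
    notes: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "boundaries": {m: list(b) if b else None
                           for m, b in self.boundaries.items()},
            "metastasis_subboundary": self.metastasis_subboundary,
            "notes": dict(self.notes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryThresholds":
        return cls(
            {m: tuple(b) if b else None for m, b in d["boundaries"].items()},
            d.get("metastasis_subboundary"),
            dict(d.get("notes", {})),
        )


@dataclass(frozen=True)
class DiagnosticCall:
    label: str
    trace: tuple[str, ...]
    categories: dict[str, str]
    margin_log2: float | None = None


def calibrate_thresholds(
    profiles: pd.DataFrame,
    levels: dict[str, dict[str, str]] | None = None,
    method: str = "chart",
) -> CategoryThresholds:
    """Fit category boundaries from a labeled cohort.

    ``profiles`` is long-format with columns patient_id, group, mirna,
    rel_expr, detected.  With ``method="chart"`` (default) each boundary is
    the log2 midpoint between adjacent chart levels of the group means; with
    ``method="gap"`` the two largest gaps between adjacent group means are
    used instead.  Deterministic given the input.
    """
    levels = levels or CHART_LEVELS
    boundaries: dict[str, tuple[float, float] | None] = {}
    notes: dict[str, str] = {}
    sub = None

    for mirna in profiles["mirna"].unique():
        part = profiles[(profiles["mirna"] == mirna) & profiles["detected"]].copy()
        # group centers are log-scale means (geometric on the 2^-dCt scale),
        # matching how ddCt averages expression
        part["log2_expr"] = np.log2(part["rel_expr"])
        means = (part.groupby("group")["log2_expr"].mean()
                 if len(part) else pd.Series(dtype=float))
        if means.empty:
            boundaries[mirna] = None
            notes[mirna] = "undetected in every calibrating group; absent/present only"
            continue
        counts = part.groupby("group")["patient_id"].nunique()
        thin = sorted(counts.index[counts < 2])
        if thin:
            notes[mirna] = f"groups with < 2 detected patients: {thin}"
        if method == "gap":
            boundaries[mirna] = _gap_boundaries(means)
        elif method == "chart":
            b, note = _chart_boundaries(mirna, means, levels)
            boundaries[mirna] = b
            if note:
                notes[mirna] = (notes.get(mirna, "") + "; " + note).lstrip("; ")
        else:
            raise ValueError(f"unknown calibration method {method!r}")
        if mirna == "miR-935":
            if {"LungMetastasis", "BreastMetastasis"} <= set(means.index):
                sub = float((means["LungMetastasis"]
                             + means["BreastMetastasis"]) / 2.0)
    if len({g for m in levels.values() for g in m}
           & set(profiles["group"].unique())) < 2:
        raise ValueError("calibration needs >= 2 groups present")
    return CategoryThresholds(boundaries, sub, notes)


def _chart_boundaries(mirna, means: pd.Series, levels) -> tuple[tuple[float, float], str]:
    lv = levels.get(mirna, {})
    by_level: dict[str, list[float]] = {"low": [], "moderate": [], "high": []}
    for g, v in means.items():
        level = lv.get(g)
        if level in by_level:
            by_level[level].append(float(v))
    note = ""
    inverted = any(
        by_level[lo] and by_level[hi] and max(by_level[lo]) >= min(by_level[hi])
        for lo, hi in (("low", "moderate"), ("moderate", "high"))
    )
    if inverted:
        # noisy cohorts can invert adjacent levels; fall back to midpoints
        # between level means so calibration stays total (and flag it)
        note = "adjacent chart levels overlap in this cohort; level-mean midpoints used"
        lvl_mean = {k: float(np.mean(v)) for k, v in by_level.items() if v}
        lo_mod = _mid(lvl_mean.get("low"),
                      lvl_mean.get("moderate", lvl_mean.get("high")))
        mod_hi = _mid(lvl_mean.get("moderate", lvl_mean.get("low")),
                      lvl_mean.get("high"))
    else:
        lo_mod = _between(by_level["low"], by_level["moderate"] + by_level["high"])
        mod_hi = _between(by_level["low"] + by_level["moderate"], by_level["high"])
    if lo_mod is None and mod_hi is None:
        center = float(np.mean(list(means)))
        lo_mod, mod_hi = center - EMPTY_LEVEL_MARGIN, center + EMPTY_LEVEL_MARGIN
    elif lo_mod is None:
        lo_mod = min(v for v in list(means)) - EMPTY_LEVEL_MARGIN
    elif mod_hi is None:
        mod_hi = max(v for v in list(means)) + EMPTY_LEVEL_MARGIN
    if lo_mod > mod_hi:
        lo_mod = mod_hi = (lo_mod + mod_hi) / 2.0
    return (float(lo_mod), float(mod_hi)), note


def _mid(a: float | None, b: float | None) -> float | None:
    if a is None or b is None:
        return None
    return (a + b) / 2.0


def _between(lower: list[float], upper: list[float]) -> float | None:
    if not lower or not upper:
        return None
    return (max(lower) + min(upper)) / 2.0


def _gap_boundaries(means: pd.Series) -> tuple[float, float]:
    vals = np.sort(np.asarray(means, dtype=float))
    if len(vals) < 3:
        mid = vals.mean() if len(vals) == 2 else vals[0]
        if len(vals) == 2:
            return float((vals[0] + vals[1]) / 2.0 - EMPTY_LEVEL_MARGIN), \
                float((vals[0] + vals[1]) / 2.0)
        return float(mid - EMPTY_LEVEL_MARGIN), float(mid + EMPTY_LEVEL_MARGIN)
    gaps = np.diff(vals)
    top2 = np.sort(np.argsort(gaps)[-2:])
    mids = [(vals[i] + vals[i + 1]) / 2.0 for i in top2]
    return float(mids[0]), float(mids[1])


def categorize(profile: dict, thresholds: CategoryThresholds) -> dict[str, str]:
    """Bin each miRNA: absent if undetected, else by the boundaries.

    ``profile`` maps miRNA -> (rel_expr, detected).  A value exactly on a
    boundary goes to the *upper* bin.
    """
    cats = {}
    for mirna, (rel_expr, detected) in profile.items():
        if not detected:
            cats[mirna] = "absent"
            continue
        b = thresholds.boundaries.get(mirna)
        if b is None:
            cats[mirna] = "moderate"   # detected but threshold-free
            continue
        x = math.log2(rel_expr)
        cats[mirna] = "low" if x < b[0] else ("moderate" if x < b[1] else "high")
    return cats


def classify_categories(
    cats: dict[str, str],
    mir935_log2: float | None = None,
    subboundary: float | None = None,
) -> DiagnosticCall:
    """Rule cascade on an already-categorized profile (deterministic)."""
    missing = [m for m in TARGET_MIRNAS if m not in cats]
    if missing:
        return DiagnosticCall(
            "Indeterminate",
            (f"missing input miRNA(s): {', '.join(missing)}",), dict(cats))

    c451, c711, c935 = cats["miR-451"], cats["miR-711"], cats["miR-935"]
    c223, c125 = cats["miR-223"], cats["miR-125b"]
    trace = []

    r1 = c451 == "low" and c711 == "moderate" and c935 in ("moderate", "high")
    trace.append(f"R1[Normal: 451 low, 711 moderate, 935 moderate/high] "
                 f"{'FIRED' if r1 else 'no'} (451={c451}, 711={c711}, 935={c935})")
    if r1:
        return DiagnosticCall("Normal", tuple(trace), dict(cats))

    r2 = (c451 in ("moderate", "high") and c711 == "moderate"
          and c935 == "moderate")
    trace.append(f"R2[Benign: 451 moderate/high, 711 moderate, 935 moderate] "
                 f"{'FIRED' if r2 else 'no'}")
    if r2:
        return DiagnosticCall("Benign", tuple(trace), dict(cats))

    r3 = c935 == "absent" and c711 == "low"
    trace.append(f"R3[Lymphoma: 935 absent, 711 low] {'FIRED' if r3 else 'no'}")
    if r3:
        return DiagnosticCall("Lymphoma", tuple(trace), dict(cats))

    r4 = c935 == "absent" and c711 in ("moderate", "high")
    trace.append(f"R4[GBM/MB: 935 absent, 711 moderate/high] "
                 f"{'FIRED' if r4 else 'no'}")
    if r4:
        if c223 == "high" and _ORD[c125] < _ORD[c223]:
            trace.append(f"R4a[223 high > 125b] FIRED (223={c223}, 125b={c125})")
            return DiagnosticCall("Glioblastoma", tuple(trace), dict(cats))
        if c125 == "high" and _ORD[c223] < _ORD[c125]:
            trace.append(f"R4b[125b high > 223] FIRED (223={c223}, 125b={c125})")
            return DiagnosticCall("Medulloblastoma", tuple(trace), dict(cats))
        trace.append(f"R4 second tier: neither miR-223 nor miR-125b dominant "
                     f"(223={c223}, 125b={c125})")
        return DiagnosticCall("Indeterminate", tuple(trace), dict(cats))

    r5 = (c935 == "high" and c223 in ("moderate", "high")
          and c125 in ("moderate", "high"))
    trace.append(f"R5[Metastasis: 935 high, 223 & 125b moderate/high] "
                 f"{'FIRED' if r5 else 'no'}")
    if r5:
        if mir935_log2 is not None and subboundary is not None:
            which = "Lung" if mir935_log2 >= subboundary else "Breast"
            trace.append(f"R5 subtype: miR-935 log2={mir935_log2:.2f} "
                         f"{'>=' if which == 'Lung' else '<'} "
                         f"sub-boundary {subboundary:.2f} -> {which}")
            return DiagnosticCall(f"Metastasis-{which}", tuple(trace), dict(cats))
        trace.append("R5 subtype: no miR-935 value/sub-boundary available")
        return DiagnosticCall("Indeterminate", tuple(trace), dict(cats))

    trace.append("no rule fired")
    return DiagnosticCall("Indeterminate", tuple(trace), dict(cats))


def classify(profile: dict, thresholds: CategoryThresholds) -> DiagnosticCall:
    """Categorize then run the cascade; records margin to nearest boundary.

    ``profile`` maps each of the five miRNAs to (rel_expr 2^-dCt, detected).
    """
    cats = categorize(profile, thresholds)
    m935 = None
    if "miR-935" in profile and profile["miR-935"][1]:
        m935 = math.log2(profile["miR-935"][0])
    call = classify_categories(cats, m935, thresholds.metastasis_subboundary)

    margins = []
    for mirna, (rel_expr, detected) in profile.items():
        b = thresholds.boundaries.get(mirna)
        if detected and b is not None:
            x = math.log2(rel_expr)
            margins.append(min(abs(x - b[0]), abs(x - b[1])))
    margin = min(margins) if margins else None
    return DiagnosticCall(call.label, call.trace, call.categories, margin)


def profiles_from_patient_table(patients: pd.DataFrame) -> dict[str, dict]:
    """Patient-level quantification table -> {patient_id: chart profile}."""
    out: dict[str, dict] = {}
    for (pid,), sub in patients.groupby(["patient_id"], sort=False):
        out[pid] = {row["mirna"]: (float(row["rel_expr"]), bool(row["detected"]))
                    for _, row in sub.iterrows()}
    return out


def evaluate_classifier(
    patients: pd.DataFrame,
    thresholds: CategoryThresholds,
) -> tuple[pd.DataFrame, pd.Series]:
    """Confusion matrix (true group x call) and per-class recall.

    Recall for a group counts calls matching ``GROUP_TO_CALL``;
    Indeterminate is tracked as its own column, never as a match.
    """
    if patients.empty:
        raise ValueError("empty cohort")
    profiles = profiles_from_patient_table(patients)
    group_of = patients.drop_duplicates("patient_id").set_index(
        "patient_id")["group"]
    groups = list(dict.fromkeys(group_of.loc[list(profiles)]))
    conf = pd.DataFrame(0, index=pd.Index(groups, name="true_group"),
                        columns=list(CALL_LABELS))
    for pid, prof in profiles.items():
        call = classify(prof, thresholds)
        conf.at[group_of[pid], call.label] += 1
    recall = pd.Series({
        g: (conf.at[g, GROUP_TO_CALL[g]] / conf.loc[g].sum()
            if g in GROUP_TO_CALL and conf.loc[g].sum() else np.nan)
        for g in groups
    }, name="recall")
    return conf, recall
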