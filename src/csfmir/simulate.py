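"""Seeded synthetic CSF miRNA datasets.

Two generators share the cohort design and effect table:

* ``simulate_ct_dataset`` — RT-PCR style cycle-threshold (Ct) triplicates for
  the five target miRNAs plus the cel-miR-248 spike-in, with a hierarchical
  noise model (patient, longitudinal sample, technical replicate) and hard
  censoring at ``ct_max``.  Absent (miRNA, group) pairs are pinned at
  ``ct_max`` for every replicate.
* ``simulate_count_matrix`` — a NanoString-like nonnegative count matrix over
  a panel of several hundred tags, the five targets embedded in a null
  background, negative-binomial noise around
  ``mu = 2^(baseline + offset) * library_size_factor``.

Randomness: one root seed; every (stream, miRNA/tag) pair draws from its own
named child stream, so adding a miRNA leaves existing values untouched and
identical seeds give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import CohortDesign
from .effects import GroupEffectTable, SPIKE_IN, stream_seed

CT_COLUMNS = ["sample_id", "patient_id", "group", "mirna", "replicate", "ct"]


@dataclass
class SimulationParams:
    """Noise magnitudes (Ct units unless stated) and sizes for the generators."""

    between_patient_sd: float = 1.0
    within_patient_sd: float = 0.5
    triplicate_sd: float = 0.3
    spike_in_mean: float = 20.0
    spike_in_sd: float = 0.15
    ct_max: float = 40.0
    n_replicates: int = 3
    panel_size: int = 300
    count_baseline_log2_range: tuple[float, float] = (3.0, 11.0)
    #: log2 expected count of each target miRNA at offset 0.
    count_target_baseline_log2: float = 8.0
    #: expected count for an absent (miRNA, group) pair.
    count_absent_floor: float = 0.5
    count_library_size_range: tuple[float, float] = (0.7, 1.3)
    count_dispersion: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("between_patient_sd", "within_patient_sd", "triplicate_sd",
                     "spike_in_sd", "count_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ct_max <= 0:
            raise ValueError("ct_max must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["count_baseline_log2_range"] = list(self.count_baseline_log2_range)
        d["count_library_size_range"] = list(self.count_library_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown simulation parameter(s): {sorted(unknown)}")
        d = dict(d)
        for k in ("count_baseline_log2_range", "count_library_size_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def simulate_ct_dataset(
    design: CohortDesign,
    effects: GroupEffectTable,
    params: SimulationParams,
) -> pd.DataFrame:
    """Long-format Ct table: sample_id, patient_id, group, mirna, replicate, ct.

    Per miRNA and patient: mean Ct = baseline - offset + N(0, between_sd);
    each longitudinal sample adds N(0, within_sd); each of the technical
    replicates adds N(0, triplicate_sd).  The spike-in is drawn independently
    of group around ``spike_in_mean``.  All values are censored at ``ct_max``.
    """
    missing = set(design.groups) - set(effects.groups)
    if missing:
        raise KeyError(f"design groups unknown to effect table: {sorted(missing)}")

    samples = design.sample_index()
    patients = design.patients
    pat_pos = {p.patient_id: i for i, p in enumerate(patients)}
    frames = []

    for mirna in effects.mirnas:
        rng = np.random.default_rng(stream_seed(params.seed, f"ct:{mirna}"))
        pat_eff = rng.normal(0.0, params.between_patient_sd, len(patients))
        rows = []
        for sample_id, patient_id, group in samples:
            if effects.is_absent(mirna, group):
                # keep the stream advancing identically so detected groups'
                # values do not depend on which groups are absent
                rng.normal(0.0, params.within_patient_sd)
                rng.normal(0.0, params.triplicate_sd, params.n_replicates)
                cts = np.full(params.n_replicates, params.ct_max)
            else:
                mu = (effects.baseline_ct[mirna]
                      - effects.offset(mirna, group)
                      + pat_eff[pat_pos[patient_id]])
                mu = mu + rng.normal(0.0, params.within_patient_sd)
                cts = mu + rng.normal(0.0, params.triplicate_sd,
                                      params.n_replicates)
                cts = np.minimum(cts, params.ct_max)
            for r, ct in enumerate(cts, start=1):
                rows.append((sample_id, patient_id, group, mirna, r, float(ct)))
        frames.append(pd.DataFrame(rows, columns=CT_COLUMNS))

    rng = np.random.default_rng(stream_seed(params.seed, "ct:spike-in"))
    rows = []
    for sample_id, patient_id, group in samples:
        mu = rng.normal(params.spike_in_mean, params.spike_in_sd)
        cts = np.minimum(
            mu + rng.normal(0.0, params.triplicate_sd, params.n_replicates),
            params.ct_max,
        )
        for r, ct in enumerate(cts, start=1):
            rows.append((sample_id, patient_id, group, SPIKE_IN, r, float(ct)))
    frames.append(pd.DataFrame(rows, columns=CT_COLUMNS))

    return pd.concat(frames, ignore_index=True)


def simulate_count_matrix(
    design: CohortDesign,
    effects: GroupEffectTable,
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NanoString-like counts: (tags x samples matrix, sample metadata).

    The five target miRNAs carry their fitted group offsets on the log2 count
    scale; the remaining ``panel_size - n_targets`` background tags are null
    (zero offset everywhere) with log2 baselines drawn uniformly from
    ``count_baseline_log2_range``.  Counts are negative binomial with
    ``var = mu + dispersion * mu^2``; ``dispersion == 0`` means deterministic
    rounded expected counts (the noise-free limit).
    """
    if params.panel_size < 100:
        raise ValueError(
            "panel must have >= 100 tags for top-100 geometric-mean "
            f"normalization (got {params.panel_size})"
        )
    targets = effects.mirnas
    if params.panel_size < len(targets):
        raise ValueError("panel smaller than the number of target miRNAs")

    samples = design.sample_index()
    sample_ids = [s[0] for s in samples]
    groups = [s[2] for s in samples]

    rng_bg = np.random.default_rng(stream_seed(params.seed, "counts:baselines"))
    n_null = params.panel_size - len(targets)
    null_base = rng_bg.uniform(*params.count_baseline_log2_range, n_null)
    tags = list(targets) + [f"tag-{i + 1:04d}" for i in range(n_null)]

    rng_lib = np.random.default_rng(stream_seed(params.seed, "counts:libsize"))
    lib = rng_lib.uniform(*params.count_library_size_range, len(samples))

    mat = np.zeros((len(tags), len(samples)))
    for i, tag in enumerate(tags):
        if tag in targets:
            mu = np.array([
                params.count_absent_floor if effects.is_absent(tag, g)
                else 2.0 ** (params.count_target_baseline_log2
                             + effects.offset(tag, g))
                for g in groups
            ])
        else:
            mu = np.full(len(samples), 2.0 ** null_base[i - len(targets)])
        mu = mu * lib
        rng = np.random.default_rng(stream_seed(params.seed, f"counts:{tag}"))
        if params.count_dispersion == 0:
            mat[i] = np.round(mu)
        else:
            r = 1.0 / params.count_dispersion
            mat[i] = rng.negative_binomial(r, r / (r + mu))

    counts = pd.DataFrame(mat, index=pd.Index(tags, name="mirna"),
                          columns=sample_ids)
    meta = pd.DataFrame(
        {"sample_id": sample_ids,
         "patient_id": [s[1] for s in samples],
         "group": groups,
         "library_size_factor": lib},
    )
    return counts, meta


# ---------------------------------------------------------------------------
# serialization


def write_ct_tsv(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, sep="\t", index=False)


def read_ct_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def write_counts_tsv(counts: pd.DataFrame, meta: pd.DataFrame,
                     counts_path, meta_path) -> None:
    counts.to_csv(counts_path, sep="\t")
    meta.to_csv(meta_path, sep="\t", index=False)


def write_rcc_like_csv(counts: pd.DataFrame, path, sample_id: str) -> None:
    """Simplified single-sample RCC-style CSV: header block + CodeSummary."""
    with open(path, "w") as fh:
        fh.write("<Header>\nFileVersion,1.7\nSoftwareVersion,csfmir\n</Header>\n")
        fh.write(f"<Sample_Attributes>\nID,{sample_id}\n</Sample_Attributes>\n")
        fh.write("<Code_Summary>\nCodeClass,Name,Accession,Count\n")
        for tag, value in counts[sample_id].items():
            fh.write(f"Endogenous,{tag},{tag},{value:g}\n")
        fh.write("</Code_Summary>\n")
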