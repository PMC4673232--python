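"""Screening stage: normalization, moderated t, FDR, candidate selection.

Counts are scaled per sample so that the geometric mean of each sample's 100
highest-count tags matches the cross-sample reference (the arithmetic mean of
those geometric means).  Differential expression uses a two-group linear
model on log2 values with empirical-Bayes variance moderation: per-tag
residual variances s^2 (df d) are shrunk toward a prior s0^2 with prior df
d0, both estimated by moment-matching the scaled-F distribution of the s^2
across tags (digamma/trigamma inversion, bisection fallback); the moderated
t has d0 + d degrees of freedom.  P-values are adjusted per contrast with
the Benjamini-Hochberg step-up.  Candidates are tags significant in at least
a strict majority of the contrasts run.

Repeated samples from one patient are collapsed to the patient mean before
model fitting, so patients — not lumbar punctures — are the experimental
units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .design import CohortDesign


@dataclass
class NormalizedMatrix:
    """Scaled counts plus per-sample factors and a log2(x+1) layer."""

    counts: pd.DataFrame          # tags x samples, scaled
    factors: pd.Series            # per sample, > 0
    log2: pd.DataFrame            # log2(scaled + 1)
    qc_flags: dict[str, str]


# ---------------------------------------------------------------------------
# I/O


def read_counts(path, meta_path=None) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read a tags-x-samples TSV (or simplified RCC-like CSV) count matrix."""
    with open(path) as fh:
        head = fh.read(8)
    if head.startswith("<Header>"):
        counts = _read_rcc_like(path)
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts.index.name = "mirna"
    if counts.index.duplicated().any():
        dup = sorted(counts.index[counts.index.duplicated()].unique())
        raise ValueError(f"duplicate tag ids: {dup}")
    try:
        counts = counts.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric counts in {path}: {exc}") from None
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t")
    return counts, meta


def _read_rcc_like(path) -> pd.DataFrame:
    sample_id, rows, in_block = None, [], False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("ID,"):
                sample_id = line.split(",", 1)[1]
            elif line == "<Code_Summary>":
                in_block = True
            elif line == "</Code_Summary>":
                in_block = False
            elif in_block and line and not line.startswith("CodeClass"):
                parts = line.split(",")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: malformed CodeSummary row")
                rows.append((parts[1], float(parts[3])))
    if sample_id is None:
        raise ValueError(f"{path}: no sample ID in RCC-like file")
    return pd.DataFrame(rows, columns=["mirna", sample_id]).set_index("mirna")


# ---------------------------------------------------------------------------
# normalization


def top100_geomean_normalize(counts: pd.DataFrame, top_n: int = 100,
                             per_sample: bool = True) -> NormalizedMatrix:
    """Scale each sample by the geometric mean of its top ``top_n`` tags.

    factor_s = mean_over_samples(g) / g_s, where g_s is the geometric mean of
    the sample's ``top_n`` largest counts.  When every top count is positive
    the factor is exactly scale-equivariant (so renormalizing is the
    identity); a sample with zeros among its top counts gets a +1
    pseudo-count before the geometric mean and a QC flag.  With
    ``per_sample=False`` the top set is the global one (tags with the
    largest total counts), applied to every sample.
    """
    if counts.shape[0] < top_n:
        raise ValueError(
            f"normalization needs >= {top_n} tags, got {counts.shape[0]}")
    x = counts.to_numpy(dtype=float)
    qc: dict[str, str] = {}

    if per_sample:
        top = np.sort(x, axis=0)[-top_n:, :]
    else:
        order = np.argsort(counts.sum(axis=1).to_numpy())[-top_n:]
        top = x[order, :]
    g = np.empty(x.shape[1])
    for j, sample in enumerate(counts.columns):
        col = top[:, j]
        if (col <= 0).any():
            qc[sample] = (f"{int((col <= 0).sum())} nonpositive counts in "
                          f"top-{top_n}; +1 pseudo-count applied")
            g[j] = np.exp(np.mean(np.log(col + 1.0)))
        else:
            g[j] = np.exp(np.mean(np.log(col)))
    factors = pd.Series(g.mean() / g, index=counts.columns, name="factor")
    scaled = counts.mul(factors, axis=1)
    return NormalizedMatrix(scaled, factors, np.log2(scaled + 1.0), qc)


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, bisection fallback)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            return float(x)
    return float(optimize.brentq(
        lambda v: special.polygamma(1, v) - y, 1e-8, 1e8))


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match s^2 ~ s0^2 * F(df, d0); returns (d0, s0^2).

    Uses the log-variance representation: for z = log s^2,
    Var(z) = trigamma(df/2) + trigamma(d0/2) and
    E(z) = log s0^2 + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2).
    All s^2 (numerically) equal => d0 = inf, complete shrinkage.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    if len(z) == 0:
        return np.inf, 0.0
    if len(z) < 2 or np.var(z, ddof=1) < 1e-15:
        return np.inf, float(np.exp(z.mean()))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * trigamma_inverse(evar)
    s0_2 = np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_2)


def collapse_to_patients(log2_layer: pd.DataFrame,
                         meta: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average a tags-x-samples log2 layer to tags-x-patients."""
    pat = meta.set_index("sample_id").loc[log2_layer.columns, "patient_id"]
    collapsed = log2_layer.T.groupby(pat.to_numpy()).mean().T
    collapsed.columns.name = "patient_id"
    pmeta = (meta[["patient_id", "group"]].drop_duplicates("patient_id")
             .set_index("patient_id").loc[collapsed.columns])
    return collapsed, pmeta.rename_axis("patient_id").reset_index()


def moderated_t_contrast(
    log2_values: pd.DataFrame,
    groups: pd.Series,
    group_a,
    group_b,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t per tag; effect = mean(A) - mean(B) (log2).

    ``group_a``/``group_b`` may be a label or a list of labels (pooled).
    ``d0_override=0`` disables shrinkage (ordinary pooled t);
    ``d0_override=np.inf`` forces complete shrinkage to s0^2.
    """
    ga = [group_a] if isinstance(group_a, str) else list(group_a)
    gb = [group_b] if isinstance(group_b, str) else list(group_b)
    if set(ga) & set(gb):
        raise ValueError("contrast groups overlap")
    groups = pd.Series(groups.to_numpy(), index=log2_values.columns)
    a = log2_values.loc[:, groups.isin(ga).to_numpy()]
    b = log2_values.loc[:, groups.isin(gb).to_numpy()]
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("both groups need >= 2 columns")

    ma, mb = a.mean(axis=1).to_numpy(), b.mean(axis=1).to_numpy()
    d = na + nb - 2
    rss = (((a.to_numpy() - ma[:, None]) ** 2).sum(axis=1)
           + ((b.to_numpy() - mb[:, None]) ** 2).sum(axis=1))
    s2 = rss / d
    d0, s0_2 = fit_f_dist(s2, d)
    if d0_override is not None:
        d0 = float(d0_override)
    if d0 == 0:
        s2_post = s2
        df_total = float(d)
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d

    se_unit = np.sqrt(1.0 / na + 1.0 / nb)
    effect = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / (np.sqrt(s2_post) * se_unit)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), 1.0, p)

    out = pd.DataFrame({
        "mirna": log2_values.index,
        "log2fc": effect,
        "t_mod": t,
        "p": p,
        "s2": s2,
        "d0": d0,
        "s0_2": s0_2,
        "df_total": df_total,
        "n_a": na,
        "n_b": nb,
    }).set_index("mirna")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    bad = np.nonzero((p < 0) | (p > 1) | np.isnan(p))[0]
    if len(bad):
        raise ValueError(f"p-value out of [0, 1] at index {bad[0]}")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# the screening battery

#: The screening comparisons: Normal against everything pooled, every pair
#: among the six analysis groups (lung and breast metastases pooled into one
#: Metastasis group, as the published comparison table does), and the
#: lung-vs-breast contrast.  17 contrasts; a strict majority is 9.
_MET = ("LungMetastasis", "BreastMetastasis")
_ANALYSIS_GROUPS: tuple[tuple[str, object], ...] = (
    ("Normal", "Normal"), ("Benign", "Benign"),
    ("Glioblastoma", "Glioblastoma"), ("Medulloblastoma", "Medulloblastoma"),
    ("Metastasis", _MET), ("Lymphoma", "Lymphoma"),
)
DEFAULT_CONTRASTS: tuple[tuple[str, object, object], ...] = (
    ("Normal_vs_AllOthers", "Normal",
     ("Benign", "Glioblastoma", "Medulloblastoma") + _MET + ("Lymphoma",)),
) + tuple(
    (f"{na}_vs_{nb}", ga, gb)
    for i, (na, ga) in enumerate(_ANALYSIS_GROUPS)
    for nb, gb in _ANALYSIS_GROUPS[i + 1:]
) + (
    ("LungMetastasis_vs_BreastMetastasis", "LungMetastasis", "BreastMetastasis"),
)


def run_contrasts(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    contrasts=DEFAULT_CONTRASTS,
    collapse_patients: bool = True,
) -> dict[str, pd.DataFrame]:
    """Normalize then run every contrast; returns {contrast name: DE table}."""
    norm = top100_geomean_normalize(counts)
    values, gmeta = (collapse_to_patients(norm.log2, meta)
                     if collapse_patients
                     else (norm.log2, meta.rename(columns={"sample_id": "unit"})))
    groups = gmeta.set_index(gmeta.columns[0]).loc[values.columns, "group"]
    return {
        name: moderated_t_contrast(values, groups, a, b)
        for name, a, b in contrasts
    }


def screen_candidates(
    results: dict[str, pd.DataFrame],
    q_threshold: float = 0.05,
    min_comparisons: int | None = None,
) -> pd.DataFrame:
    """Tags significant (q < threshold) in >= min_comparisons contrasts.

    Default ``min_comparisons`` is a strict majority of the contrasts run.
    Ranked by number of significant contrasts, then by best q.
    """
    if not results:
        raise ValueError("need at least one computed contrast")
    n = len(results)
    if min_comparisons is None:
        min_comparisons = n // 2 + 1
    sig = pd.DataFrame({name: df["q"] < q_threshold
                        for name, df in results.items()})
    best_q = pd.DataFrame({name: df["q"] for name, df in results.items()}).min(axis=1)
    tally = sig.sum(axis=1)
    out = pd.DataFrame({"n_significant": tally, "best_q": best_q,
                        "n_contrasts": n})
    out = out[out["n_significant"] >= min_comparisons]
    return out.sort_values(["n_significant", "best_q"],
                           ascending=[False, True])
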