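"""Screening stage on the simulated count matrix.

Normalizes by the top-100 geometric mean, runs the 17 screening contrasts
with the empirical-Bayes moderated t, adjusts with Benjamini-Hochberg, and
selects candidates significant in a strict majority of contrasts.  The five
validated miRNAs should head the candidate list.
"""

from pathlib import Path

import pandas as pd

from csfmir.nanostring import read_counts, run_contrasts, screen_candidates

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "screen"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts, meta = read_counts(BASE / "cohort" / "counts.tsv",
                               BASE / "cohort" / "sample_metadata.tsv")
    results = run_contrasts(counts, meta)
    tables = []
    for name, df in results.items():
        t = df.reset_index()
        t.insert(1, "contrast", name)
        tables.append(t)
    de = pd.concat(tables, ignore_index=True)
    de.to_csv(OUT / "de_results.tsv", sep="\t", index=False)

    candidates = screen_candidates(results)
    candidates.to_csv(OUT / "candidates.tsv", sep="\t")
    print(f"ran {len(results)} contrasts over {counts.shape[0]} tags")
    print("candidates significant in a strict majority of contrasts:")
    print(candidates.to_string())


if __name__ == "__main__":
    main()
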