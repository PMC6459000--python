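"""Cross-model enrichment ranking of screened drugs.

A drug's evidence is the number k of models whose geroprotective index
for it exceeds the mean-absolute-deviation cutoff of the pooled index
distribution.  Enrichment of k against the pooled distribution is an
upper-tail hypergeometric test (population = all drug x model
predictions, successes = all above-cutoff predictions, draws = the
drug's own predictions), corrected across drugs by Benjamini-Hochberg.
Candidate lists are validated against a known-geroprotector set with a
one-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def mad_cutoff(values) -> float:
    """Mean absolute deviation around the mean of the pooled index
    values (NaN cells excluded)."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no index values to pool")
    return float(np.mean(np.abs(v - v.mean())))


def count_supporting_models(
    index_matrix: pd.DataFrame, cutoff: float
) -> pd.DataFrame:
    """Per drug: k = number of non-missing model cells with index
    strictly above ``cutoff``, and M = number of non-missing cells."""
    above = (index_matrix > cutoff).sum(axis=1)  # NaN > c is False
    m_eff = index_matrix.notna().sum(axis=1)
    return pd.DataFrame({"k": above.astype(int), "M": m_eff.astype(int)})


def enrichment_pvalues(
    counts: pd.DataFrame,
    total_predictions: int,
    total_above: int,
    method: str = "fdr_bh",
    binomial: bool = False,
) -> pd.DataFrame:
    """Upper-tail enrichment p per drug plus multiplicity-corrected q.

    p = P(X >= k) for X hypergeometric with population
    ``total_predictions``, successes ``total_above`` and draws M (the
    drug's prediction count); k = 0 gives p = 1.  ``binomial`` switches
    to the binomial approximation X ~ Bin(M, total_above/total).
    q values are Benjamini-Hochberg by default (``method`` is passed to
    statsmodels ``multipletests``).
    """
    if total_above > total_predictions:
        raise ValueError("total_above exceeds total_predictions")
    if ((counts["k"] > counts["M"]) | (counts["k"] > total_above)).any():
        raise ValueError("per-drug count k exceeds draws or total successes")
    k = counts["k"].to_numpy()
    M = counts["M"].to_numpy()
    if binomial:
        p = stats.binom.sf(k - 1, M, total_above / total_predictions)
    else:
        p = stats.hypergeom.sf(k - 1, total_predictions, total_above, M)
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method=method)[1]
    out = counts.copy()
    out["p"] = p
    out["q"] = q
    return out


def rank_drugs(stats_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Sort drugs by (q asc, p asc, k desc, name asc) and flag
    significance at q <= alpha.  The drug name is the index."""
    required = {"k", "M", "p", "q"}
    if not required <= set(stats_table.columns):
        raise ValueError(f"ranking needs columns {sorted(required)}")
    out = stats_table.copy()
    out["_name"] = out.index.astype(str)
    out = out.sort_values(["q", "p", "k", "_name"], ascending=[True, True, False, True])
    out = out.drop(columns="_name")
    out["rank"] = np.arange(1, len(out) + 1)
    out["significant"] = out["q"] <= alpha
    return out


def candidate_list(ranking: pd.DataFrame) -> list[str]:
    return ranking.index[ranking["significant"]].tolist()


@dataclass
class OverlapTestResult:
    """One-sided Fisher enrichment of candidates in a known set."""

    table: np.ndarray  # 2x2: [[both, cand only], [known only, neither]]
    p_value: float
    observed_overlap: int
    expected_overlap: float

    def as_dict(self) -> dict:
        return {
            "table": self.table.tolist(),
            "p_value": self.p_value,
            "observed_overlap": self.observed_overlap,
            "expected_overlap": self.expected_overlap,
        }


def known_set_overlap_test(
    candidates, known_set, universe_size: int
) -> OverlapTestResult:
    """Build the candidate x known 2x2 contingency over a universe of
    ``universe_size`` drugs and test enrichment one-sidedly.

    Matching is case-insensitive; duplicates are removed.
    """
    if universe_size <= 0:
        raise ValueError("empty universe")
    cand = {str(c).lower() for c in candidates}
    known = {str(k).lower() for k in known_set}
    both = len(cand & known)
    cand_only = len(cand - known)
    known_only = len(known - cand)
    neither = universe_size - both - cand_only - known_only
    if neither < 0:
        raise ValueError("universe smaller than the union of candidate and known sets")
    table = np.array([[both, cand_only], [known_only, neither]])
    _, p = stats.fisher_exact(table, alternative="greater")
    expected = len(cand) * len(known) / universe_size
    return OverlapTestResult(
        table=table,
        p_value=float(p),
        observed_overlap=both,
        expected_overlap=float(expected),
    )
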