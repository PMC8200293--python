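"""Fold changes, a two-group negative-binomial Wald test, BH-FDR, DE calls,
and Fisher gene-set overlap.

The test deliberately stays far simpler than a full NB generalized linear
model: normalized group means are compared on the log2 scale with a
delta-method standard error built from the NB variance function
``V(mu) = mu + alpha * mu**2``.  The dispersion ``alpha`` is a single common
value, the genome-wide mean of per-gene method-of-moments estimates: with
two or three replicates per group a per-gene variance estimate has so few
degrees of freedom that a normal-reference Wald statistic becomes strongly
anticonservative, whereas the common estimate borrows thousands of degrees of
freedom across genes and calibrates the null rejection rate (see
docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .normalization import SizeFactors, normalize_counts

LN2 = math.log(2.0)


def _group_columns(
    samples: Sequence[str],
    groups: Mapping[str, str],
    treated: str,
    control: str,
) -> Tuple[list, list]:
    t_cols = [s for s in samples if groups.get(s) == treated]
    c_cols = [s for s in samples if groups.get(s) == control]
    if not t_cols or not c_cols:
        raise DataError(
            f"both groups need >= 1 sample; got {len(t_cols)} treated "
            f"({treated!r}) and {len(c_cols)} control ({control!r})"
        )
    return t_cols, c_cols


def log2_fold_changes(
    normalized: pd.DataFrame,
    groups: Mapping[str, str],
    treated: str,
    control: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean treated + pc) / (mean control + pc))."""
    if pseudocount <= 0:
        raise DataError("pseudocount must be positive")
    t_cols, c_cols = _group_columns(normalized.columns, groups, treated, control)
    m_t = normalized[t_cols].mean(axis=1)
    m_c = normalized[c_cols].mean(axis=1)
    lfc = np.log2((m_t + pseudocount) / (m_c + pseudocount))
    lfc.name = "log2_fc"
    return lfc


def nb_test(
    counts: pd.DataFrame,
    s: SizeFactors,
    groups: Mapping[str, str],
    treated: str,
    control: str,
    pseudocount: float = 1.0,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Two-group Wald test on size-factor normalized counts.

    Returns a frame with ``base_mean``, ``log2_fc``, ``se``, ``stat`` and
    ``p_value`` per gene.  Genes whose raw counts are zero in every sample of
    both groups get an undefined (NaN) p-value and are meant to be excluded
    from multiple testing.  ``dispersion`` overrides the common
    method-of-moments estimate when given.
    """
    t_cols, c_cols = _group_columns(counts.columns, groups, treated, control)
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise DataError("nb_test needs >= 2 samples per group")
    norm = normalize_counts(counts[t_cols + c_cols], _subset_factors(s, t_cols + c_cols))
    n1, n2 = len(t_cols), len(c_cols)
    g1 = norm[t_cols].to_numpy(float)
    g2 = norm[c_cols].to_numpy(float)
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1 = g1.var(axis=1, ddof=1)
    v2 = g2.var(axis=1, ddof=1)
    v_pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    m_pooled = (m1 + m2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_gene = np.where(
            m_pooled > 0,
            np.maximum(0.0, (v_pooled - m_pooled) / np.maximum(m_pooled, 1e-300) ** 2),
            np.nan,
        )
    if dispersion is None:
        valid = np.isfinite(alpha_gene)
        dispersion = float(np.mean(alpha_gene[valid])) if valid.any() else 0.0
    elif dispersion < 0:
        raise DataError("dispersion must be >= 0")
    lfc = np.log2((m1 + pseudocount) / (m2 + pseudocount))
    var1 = m1 + dispersion * m1**2
    var2 = m2 + dispersion * m2**2
    se = np.sqrt(
        var1 / (n1 * (m1 + pseudocount) ** 2) + var2 / (n2 * (m2 + pseudocount) ** 2)
    ) / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(stat))
    all_zero = (counts[t_cols + c_cols].to_numpy(float).sum(axis=1) == 0)
    stat = np.where(all_zero, np.nan, stat)
    p = np.where(all_zero, np.nan, p)
    return pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2_fc": lfc,
            "se": se,
            "stat": stat,
            "p_value": p,
            "all_zero": all_zero,
        },
        index=counts.index,
    )


def _subset_factors(s: SizeFactors, samples: Sequence[str]) -> SizeFactors:
    return SizeFactors(
        factors=s.factors.loc[list(samples)],
        mode=s.mode,
        reference_gene_count=s.reference_gene_count,
    )


def bh_adjust(p: Union[Sequence[float], np.ndarray, pd.Series]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, order-preserving; NaN passes through."""
    arr = np.asarray(pd.Series(p).to_numpy(), dtype=float)
    finite = ~np.isnan(arr)
    if ((arr[finite] < 0) | (arr[finite] > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    if finite.any():
        from statsmodels.stats.multitest import multipletests

        out[finite] = multipletests(arr[finite], method="fdr_bh")[1]
    return out


def call_de(
    lfc: pd.Series,
    fdr: pd.Series,
    fdr_threshold: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.Series:
    """Classify genes as up / down / ns at a joint FDR and fold-change cut.

    ``up`` requires fdr <= threshold and a fold change (2**lfc) of at least
    ``fc_threshold``; ``down`` is symmetric.  Genes with undefined FDR are ns.
    """
    if fc_threshold < 1:
        raise DataError("fc_threshold must be >= 1")
    if fdr_threshold <= 0:
        raise DataError("fdr_threshold must be positive")
    lfc_cut = math.log2(fc_threshold)
    passed = fdr.notna() & (fdr <= fdr_threshold)
    status = pd.Series("ns", index=lfc.index, name="status")
    status[passed & (lfc >= lfc_cut)] = "up"
    status[passed & (lfc <= -lfc_cut)] = "down"
    return status


@dataclass
class OverlapTest:
    """A one-sided (enrichment) Fisher test of two gene sets in a universe."""

    n_a: int
    n_b: int
    n_overlap: int
    universe_size: int
    odds_ratio: float
    p_value: float


def overlap_fisher_counts(
    n_a: int,
    n_b: int,
    n_overlap: int,
    universe_size: int = 6049,
) -> OverlapTest:
    """Enrichment test from the 2x2 table implied by set sizes and overlap.

    The p-value is the exact hypergeometric upper tail P(X >= n_overlap); the
    sample odds ratio applies a 0.5 continuity correction when a cell is zero.
    The default universe is the 6,049-gene S. cerevisiae catalogue.
    """
    for name, v in (("n_a", n_a), ("n_b", n_b), ("n_overlap", n_overlap),
                    ("universe_size", universe_size)):
        if v < 0:
            raise DataError(f"{name} must be non-negative")
    if n_overlap > min(n_a, n_b):
        raise DataError("n_overlap cannot exceed the smaller set")
    if max(n_a, n_b) > universe_size or n_a + n_b - n_overlap > universe_size:
        raise DataError("sets do not fit in the universe")
    p = float(stats.hypergeom.sf(n_overlap - 1, universe_size, n_a, n_b))
    a = n_overlap
    b = n_a - n_overlap
    c = n_b - n_overlap
    d = universe_size - n_a - n_b + n_overlap
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds = (a * d) / (b * c)
    return OverlapTest(n_a=n_a, n_b=n_b, n_overlap=n_overlap,
                       universe_size=universe_size, odds_ratio=float(odds),
                       p_value=min(p, 1.0))


def overlap_fisher(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe_size: int = 6049,
) -> OverlapTest:
    """Enrichment Fisher test for the overlap of two gene-id sets."""
    a: Set[str] = set(set_a)
    b: Set[str] = set(set_b)
    return overlap_fisher_counts(len(a), len(b), len(a & b), universe_size)
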