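"""Familial correlations per relative-pair type.

Symmetric relations (spouse, sister-sister, brother-brother, and the
sex-agnostic sibling / half-sibling / cousin buckets) are estimated by the
double-entry intraclass correlation: every pair contributes both orderings
and a Pearson correlation is taken over the doubled set.  Asymmetric
relations (the four parent-offspring dyads, brother-sister, grandparent,
avuncular) use the interclass Pearson correlation over (senior, junior)
ordered pairs.  p-values come from the Fisher z transform with effective
sample size equal to the number of distinct pairs; an optional
cluster bootstrap over families gives a dependence-robust standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import SYMMETRIC_RELATIONS, RelativePair
from .traits import TraitTable

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class PairCorrelation:
    """Correlation of one trait within one relative-pair type."""

    relation: str
    trait: str
    r: float
    n_pairs: int
    se: float
    p: float
    significant: bool
    method: str  # "intraclass" (double-entry) or "interclass"
    n_dropped: int = 0
    se_bootstrap: float | None = None
    reason: str | None = None  # set when r is undefined


def pair_values(
    pairs: Iterable[RelativePair], traits: TraitTable, trait: str
) -> tuple[pd.DataFrame, int]:
    """Join a pair list against one trait column.

    Returns a frame with columns (fid, x, y) — x the senior role, y the
    junior — plus the count of pairs dropped because either member lacks a
    non-missing value (pairwise-complete deletion, no imputation).
    """
    series = traits.trait_vector(trait)  # KeyError if absent
    lookup = series.to_dict()
    rows = []
    dropped = 0
    for p in pairs:
        x = lookup.get((p.fid, p.iid_a), np.nan)
        y = lookup.get((p.fid, p.iid_b), np.nan)
        if np.isnan(x) or np.isnan(y):
            dropped += 1
            continue
        rows.append((p.fid, x, y))
    df = pd.DataFrame(rows, columns=["fid", "x", "y"])
    if dropped:
        logger.info("trait %s: dropped %d incomplete pairs", trait, dropped)
    return df, dropped


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def _double_entry_r(x: np.ndarray, y: np.ndarray) -> float:
    return _pearson(np.concatenate([x, y]), np.concatenate([y, x]))


def correlation(
    duples: pd.DataFrame,
    relation: str,
    trait: str = "",
    method: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    bootstrap: int = 0,
    seed: int | None = None,
    n_dropped: int = 0,
) -> PairCorrelation:
    """Estimate the familial correlation for one pair type.

    ``duples`` is the (fid, x, y) frame from :func:`pair_values`.  The
    estimator defaults to double-entry intraclass for symmetric relations
    and interclass Pearson otherwise.  ``bootstrap > 0`` adds a cluster
    bootstrap over families (pairs sharing an individual are not
    independent; the Fisher-z p treats them as if they were, matching the
    conventional reporting style).
    """
    n = len(duples)
    if n < 3:
        raise ValueError(f"{relation}: need >=3 complete pairs, got {n}")
    if method is None:
        method = "intraclass" if relation in SYMMETRIC_RELATIONS else "interclass"
    if method not in ("intraclass", "interclass"):
        raise ValueError(f"unknown method {method!r}")
    x = duples["x"].to_numpy(dtype=float)
    y = duples["y"].to_numpy(dtype=float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        if method == "intraclass" and np.ptp(np.concatenate([x, y])) > 0.0:
            pass  # double-entry margins are the pooled vector: still defined
        else:
            return PairCorrelation(
                relation, trait, np.nan, n, np.nan, np.nan, False, method,
                n_dropped=n_dropped, reason="zero variance on a margin",
            )
    estimator = _double_entry_r if method == "intraclass" else _pearson
    r = estimator(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    # Fisher z with effective N = number of distinct pairs
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        p = float(2.0 * stats.norm.sf(abs(z) * np.sqrt(n - 3)))
    else:
        p = 0.0 if abs(r) == 1.0 else 1.0
    se = float(np.sqrt((1.0 - r**2) / (n - 2))) if n > 2 else np.nan
    se_boot = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        fids = duples["fid"].to_numpy()
        unique_fids = np.unique(fids)
        groups = {f: np.flatnonzero(fids == f) for f in unique_fids}
        reps = np.empty(bootstrap)
        for b in range(bootstrap):
            take = rng.choice(unique_fids, size=len(unique_fids), replace=True)
            idx = np.concatenate([groups[f] for f in take])
            if np.ptp(x[idx]) == 0.0 or np.ptp(y[idx]) == 0.0:
                reps[b] = np.nan
                continue
            reps[b] = estimator(x[idx], y[idx])
        se_boot = float(np.nanstd(reps, ddof=1))
    return PairCorrelation(
        relation=relation, trait=trait, r=r, n_pairs=n, se=se, p=p,
        significant=bool(p < alpha), method=method, n_dropped=n_dropped,
        se_bootstrap=se_boot,
    )


def correlation_matrix(
    pairs: Sequence[RelativePair],
    traits: TraitTable,
    relations: Sequence[str] | None = None,
    trait_names: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    blank_nonsignificant: bool = False,
    bootstrap: int = 0,
    seed: int | None = None,
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, list[PairCorrelation]]:
    """Relation x trait grid of familial correlations.

    Returns the r matrix (relations as rows) and the full per-cell
    records.  Cells below the significance threshold are flagged in the
    records; with ``blank_nonsignificant`` they are blanked (NaN) in the
    matrix, mirroring reports that show significant correlations only.
    """
    if relations is None:
        seen = []
        for p in pairs:
            if p.relation not in seen:
                seen.append(p.relation)
        relations = seen
    if trait_names is None:
        trait_names = traits.trait_names
    by_relation: dict[str, list[RelativePair]] = {rel: [] for rel in relations}
    for p in pairs:
        if p.relation in by_relation:
            by_relation[p.relation].append(p)
    cells: list[PairCorrelation] = []
    mat = pd.DataFrame(index=list(relations), columns=list(trait_names), dtype=float)
    for rel in relations:
        for trait in trait_names:
            duples, dropped = pair_values(by_relation[rel], traits, trait)
            if len(duples) < min_pairs:
                logger.warning("%s x %s: only %d complete pairs, skipped",
                               rel, trait, len(duples))
                cells.append(PairCorrelation(
                    rel, trait, np.nan, len(duples), np.nan, np.nan, False,
                    "intraclass" if rel in SYMMETRIC_RELATIONS else "interclass",
                    n_dropped=dropped, reason="too few pairs",
                ))
                continue
            cell = correlation(
                duples, rel, trait, alpha=alpha, bootstrap=bootstrap,
                seed=seed, n_dropped=dropped,
            )
            cells.append(cell)
            show = cell.r
            if blank_nonsignificant and not cell.significant:
                show = np.nan
            mat.loc[rel, trait] = show
    return mat, cells


def cells_to_frame(cells: Iterable[PairCorrelation]) -> pd.DataFrame:
    """Long-format TSV-ready table (relation, trait, r, n_pairs, se, p, ...)."""
    return pd.DataFrame(
        {
            "relation": c.relation,
            "trait": c.trait,
            "r": c.r,
            "n_pairs": c.n_pairs,
            "se": c.se,
            "p": c.p,
            "significant": c.significant,
            "method": c.method,
            "n_dropped": c.n_dropped,
            "se_bootstrap": c.se_bootstrap,
            "reason": c.reason,
        }
        for c in cells
    )
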