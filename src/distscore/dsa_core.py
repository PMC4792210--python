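"""Distance scoring analysis (DSA).

For every unordered Cα–Cα pair of a fixed bundle, across an ensemble of
aligned chains, DSA computes the mean distance μ, its standard deviation σ and
the score μ/σ — the inverse of the coefficient of variation.  A high score
means the spacing between the two residues is conserved across the ensemble;
an ensemble of rigid copies has σ = 0 and the score is reported as +inf.
Pairs are then ranked by score and summarised as cumulative-ratio curves per
helix (intrahelical pairs) or per helix pair (interhelical pairs).

All per-chain distance vectors use the canonical condensed pair order of
:class:`~distscore.bundle_model.PairIndex` (identical to scipy's ``pdist``
order), so entry k of every vector refers to the same residue pair.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .bundle_model import DataError, PairIndex, enumerate_pairs
from .structure_io import ChainBundle

logger = logging.getLogger("distscore")

DEFAULT_MIN_CHAINS = 3
DEFAULT_TOP_N = 1000
#: std (Å) at or below this is treated as exactly zero (score +inf).  Rigid
#: copies of a chain differ by rotation round-off near machine epsilon, many
#: orders below the 1e-3 Å precision of coordinate files.
ZERO_STD_TOL = 1e-9


def chain_distance_vector(chain: ChainBundle, pairs: PairIndex) -> np.ndarray:
    """Condensed vector of Euclidean Cα–Cα distances (Å) for one chain.

    Entry k is the distance of pair k; NaN where either residue is masked.
    """
    if pairs.bundle.total_length != chain.bundle.total_length:
        raise DataError(
            f"{chain.structure_id}/{chain.chain_id}: chain does not conform to "
            "the pair index's bundle definition"
        )
    if chain.present.all():
        return pdist(chain.coords)
    coords = np.where(chain.present[:, None], chain.coords, 0.0)
    d = pdist(coords)
    defined = chain.present[pairs.i] & chain.present[pairs.j]
    d[~defined] = np.nan
    return d


def _distance_matrix(ensemble: list[ChainBundle], pairs: PairIndex) -> np.ndarray:
    """(M, P) matrix of per-chain condensed distance vectors."""
    return np.stack([chain_distance_vector(c, pairs) for c in ensemble])


def pair_statistics(
    ensemble: list[ChainBundle],
    pairs: PairIndex | None = None,
    *,
    std_convention: str = "population",
    min_chains: int = DEFAULT_MIN_CHAINS,
) -> pd.DataFrame:
    """Per-pair ensemble statistics and DSA scores.

    Parameters
    ----------
    ensemble
        ≥ 2 chains sharing one bundle definition.
    std_convention
        'population' (divide by n, default) or 'sample' (n − 1).
    min_chains
        Pairs defined in fewer chains get NaN score (mean/std still reported
        where computable).

    Returns a DataFrame with one row per pair: pair_index, label_i, label_j,
    kind, group, n_chains, mean, std, score.  score is +inf where std == 0.
    """
    if len(ensemble) < 2:
        raise DataError(f"need at least 2 chains, got {len(ensemble)}")
    bundle = ensemble[0].bundle
    for c in ensemble[1:]:
        if c.bundle.total_length != bundle.total_length or tuple(
            h.helix_id for h in c.bundle.helices
        ) != tuple(h.helix_id for h in bundle.helices):
            raise DataError(
                f"{c.structure_id}/{c.chain_id}: bundle definition differs "
                "from the rest of the ensemble"
            )
    if std_convention not in ("population", "sample"):
        raise DataError(f"unknown std convention {std_convention!r}")
    if pairs is None:
        pairs = enumerate_pairs(bundle)

    dmat = _distance_matrix(ensemble, pairs)  # (M, P)
    n_chains = np.sum(~np.isnan(dmat), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice means
        mean = np.nanmean(dmat, axis=0)
        ddof = 0 if std_convention == "population" else 1
        std = np.nanstd(dmat, axis=0, ddof=ddof)
        std = np.where(std <= ZERO_STD_TOL, 0.0, std)
        score = np.where(std == 0.0, np.inf, mean / std)
    score = np.where(n_chains < min_chains, np.nan, score)
    n_undef = int(np.sum(np.isnan(score)))
    if n_undef:
        logger.warning(
            "%d of %d pairs have undefined score (defined in < %d chains)",
            n_undef,
            len(pairs),
            min_chains,
        )
    labels = [lab.render() for lab in bundle.positions]
    return pd.DataFrame(
        {
            "pair_index": np.arange(len(pairs)),
            "label_i": np.array(labels, dtype=object)[pairs.i],
            "label_j": np.array(labels, dtype=object)[pairs.j],
            "kind": pairs.kind,
            "group": pairs.group,
            "n_chains": n_chains,
            "mean": mean,
            "std": std,
            "score": score,
        }
    )


def rank_pairs(stats: pd.DataFrame) -> pd.DataFrame:
    """Rank pairs by descending score.

    Infinite scores rank first (among themselves in canonical pair order);
    finite ties also break by canonical pair order.  Undefined (NaN) scores
    are excluded and reported via the log.  The result carries a 1-based
    'rank' column and is stable across runs.
    """
    defined = stats[~stats["score"].isna()].copy()
    n_excluded = len(stats) - len(defined)
    if n_excluded:
        logger.warning("rank_pairs: excluded %d undefined-score pairs", n_excluded)
    order = np.lexsort((defined["pair_index"].to_numpy(), -defined["score"].to_numpy()))
    ranked = defined.iloc[order].reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return ranked


def cumulative_ratio(
    ranked: pd.DataFrame,
    top_n: int = DEFAULT_TOP_N,
    *,
    group_col: str = "group",
    denominator: str = "group",
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group cumulative ratio curves over the top-ranked pairs.

    curve[g][r] = (# group-g pairs among ranks 1..r) / total, where the total
    is the number of group-g pairs in the full ranked set (``denominator =
    'group'``, default) or the grand total of ranked pairs (``'grand'``).
    Rows are ranks 1..top_n; each curve is non-decreasing and within [0, 1].
    """
    if top_n < 1 or top_n > len(ranked):
        raise DataError(
            f"top_n {top_n} outside 1..{len(ranked)} (number of ranked pairs)"
        )
    if denominator not in ("group", "grand"):
        raise DataError(f"unknown denominator {denominator!r}")
    all_groups = list(groups) if groups is not None else sorted(
        ranked[group_col].unique()
    )
    head = ranked.iloc[:top_n]
    out = {}
    for g in all_groups:
        total = int((ranked[group_col] == g).sum()) if denominator == "group" else len(ranked)
        hits = (head[group_col] == g).to_numpy()
        if total == 0:
            logger.warning("cumulative_ratio: group %r is empty; curve of zeros", g)
            out[g] = np.zeros(top_n)
        else:
            out[g] = np.cumsum(hits) / total
    return pd.DataFrame(out, index=pd.RangeIndex(1, top_n + 1, name="rank"))


def score_distance_table(stats: pd.DataFrame) -> pd.DataFrame:
    """Rows of (mean distance, score, class) for score-vs-distance plots.

    One row per defined-score pair; intrahelical and interhelical pairs remain
    distinguishable through the 'kind' column.
    """
    defined = stats[~stats["score"].isna()]
    return defined[["mean", "score", "kind", "group"]].reset_index(drop=True)
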