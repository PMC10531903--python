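"""Cross-cohort DMP comparison: overlap percentage matrices, shared-count
tables, per-cohort methylation profiles, and a median-aggregated
Euclidean cohort tree.

The overlap matrix is asymmetric by design: entry (y, x) is the
percentage of cohort y's DMPs also present in cohort x's DMPs, using all
DMPs of each cohort.  The cohort tree instead restricts each cohort to
its top-N DMPs (default 500, ranked by p-value; cohorts with fewer
contribute all of them), represents each cohort by the per-probe median
methylation difference across its samples over the union feature space
(0 where a cohort did not measure a probe), and clusters cohorts by
Euclidean distance with average linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class CohortSignature:
    """One cohort's DMP set with per-probe methylation differences."""

    cohort_id: str
    dmp_deltas: dict[str, float]
    dmp_pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def dmp_ids(self) -> set[str]:
        return set(self.dmp_deltas)

    @property
    def n_dmps(self) -> int:
        return len(self.dmp_deltas)

    @property
    def mean_delta(self) -> float:
        return float(np.mean(list(self.dmp_deltas.values())))

    def top_dmps(self, n: int) -> list[str]:
        """Top-n DMP ids by ascending p-value (|Δβ| descending when no
        p-values are recorded); all DMPs when fewer than n."""
        if self.n_dmps <= n:
            return sorted(self.dmp_deltas)
        if self.dmp_pvalues:
            key = lambda pid: (self.dmp_pvalues.get(pid, 1.0), pid)
        else:
            key = lambda pid: (-abs(self.dmp_deltas[pid]), pid)
        return sorted(self.dmp_deltas, key=key)[:n]


def overlap_matrix(signatures: list[CohortSignature]) -> pd.DataFrame:
    """entry(y, x) = 100 × |y ∩ x| / |y|; diagonal 100."""
    if len(signatures) < 2:
        raise ValueError("need >= 2 cohorts")
    for s in signatures:
        if s.n_dmps == 0:
            raise ValueError(f"cohort {s.cohort_id!r} has an empty DMP set")
    ids = [s.cohort_id for s in signatures]
    sets = {s.cohort_id: s.dmp_ids for s in signatures}
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for y in ids:
        for x in ids:
            mat.loc[y, x] = 100.0 * len(sets[y] & sets[x]) / len(sets[y])
    return mat


def shared_counts(signatures: list[CohortSignature]) -> pd.DataFrame:
    """Symmetric pairwise intersection counts, zero diagonal."""
    if len(signatures) < 2:
        raise ValueError("need >= 2 cohorts")
    ids = [s.cohort_id for s in signatures]
    sets = {s.cohort_id: s.dmp_ids for s in signatures}
    mat = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i, y in enumerate(ids):
        for x in ids[i + 1:]:
            k = len(sets[y] & sets[x])
            mat.loc[y, x] = k
            mat.loc[x, y] = k
    return mat


def methylation_profile(sig: CohortSignature) -> tuple[np.ndarray, float]:
    """Sorted Δβ values plus the cohort mean (the 'red line'); a cohort is
    relatively hypomethylated iff the mean is negative."""
    if sig.n_dmps == 0:
        raise ValueError("empty signature")
    deltas = np.sort(np.asarray(list(sig.dmp_deltas.values()), dtype=float))
    return deltas, float(deltas.mean())


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(link)

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return (f"({rec(node.left, node.dist)},"
                f"{rec(node.right, node.dist)}):{length:.6g}")

    return rec(tree, tree.dist) + ";"


def cohort_tree(
    signatures: list[CohortSignature],
    sample_deltas: dict[str, pd.DataFrame],
    top_n: int = 500,
) -> tuple[str, pd.DataFrame]:
    """Median-aggregated Euclidean cohort tree over union top-N DMPs.

    ``sample_deltas[cohort]`` holds per-sample beta differences from the
    cohort's control mean (probes × samples).  Returns ``(newick,
    leaf_attributes)`` with per-cohort n_dmps and mean_delta; cohorts are
    processed in sorted-id order so the tree is input-order invariant.
    """
    if len(signatures) < 3:
        raise ValueError("need >= 3 cohorts for a tree")
    signatures = sorted(signatures, key=lambda s: s.cohort_id)
    union: list[str] = sorted(set().union(
        *(s.top_dmps(top_n) for s in signatures)))
    rows = []
    for s in signatures:
        deltas = sample_deltas[s.cohort_id]
        med = deltas.median(axis=1).reindex(union).fillna(0.0)
        rows.append(med.to_numpy(dtype=float))
    x = np.vstack(rows)
    link = hierarchy.linkage(pdist(x, metric="euclidean"), method="average")
    labels = [s.cohort_id for s in signatures]
    newick = _linkage_to_newick(link, labels)
    attrs = pd.DataFrame({
        "cohort_id": labels,
        "n_dmps": [s.n_dmps for s in signatures],
        "mean_delta": [s.mean_delta for s in signatures],
    }).set_index("cohort_id")
    return newick, attrs


def signature_from_dmp_table(
    cohort_id: str,
    stats: pd.DataFrame,
    max_p_adjusted: float = 0.01,
    min_abs_delta: float = 0.05,
) -> CohortSignature:
    """Build a cohort signature by thresholding a per-probe DMP table on
    |Δβ| and BH-adjusted p (the genome-wide DMP-set definition)."""
    sel = stats[(stats["p_adjusted"] < max_p_adjusted)
                & (stats["delta_beta"].abs() >= min_abs_delta)]
    return CohortSignature(
        cohort_id=cohort_id,
        dmp_deltas=sel["delta_beta"].to_dict(),
        dmp_pvalues=sel["p_value"].to_dict(),
    )
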