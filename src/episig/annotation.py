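"""Genomic-context annotation of probes and regions, and the χ² test
comparing a DMP context distribution against the array background.

CGI contexts follow the conventional band definitions: a position inside
a CpG island is ``island``; within (0, 2000] bp of the nearest island it
is ``shore``; within (2000, 4000] bp it is ``shelf``; anything farther is
``inter_cgi``.  Gene contexts are strand-aware: ``promoter`` covers up to
1 kb upstream of a TSS, ``promoter_plus`` 1–5 kb upstream, and any
position inside a gene span is ``gene_body``; precedence is
promoter > promoter_plus > gene_body > intergenic, with the nearest TSS
deciding among overlapping promoter claims.

All internal coordinates are 0-based half-open (BED-style); 1-based
manifest positions are converted once at the entry points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

CGI_CONTEXTS = ("island", "shore", "shelf", "inter_cgi")
GENE_CONTEXTS = ("promoter", "promoter_plus", "gene_body", "intergenic")

SHORE_MAX_BP = 2000
SHELF_MAX_BP = 4000
PROMOTER_MAX_BP = 1000
PROMOTER_PLUS_MAX_BP = 5000


def _positions_frame(positions: pd.DataFrame) -> pd.DataFrame:
    """Normalize a manifest-like frame to probe_id/chrom/pos0."""
    out = positions[["probe_id", "chrom", "pos"]].reset_index(drop=True)
    out["pos0"] = out["pos"].astype(int) - 1
    return out


def annotate_cgi(positions: pd.DataFrame,
                 cgi_intervals: pd.DataFrame) -> pd.DataFrame:
    """CGI context per probe; returns probe_id-indexed frame with
    ``cgi_context`` and ``cgi_distance`` (0 inside an island)."""
    pos = _positions_frame(positions)
    dist = np.full(len(pos), np.inf)
    for chrom, sub in pos.groupby("chrom", sort=False):
        ivals = cgi_intervals[cgi_intervals["chrom"] == chrom]
        if ivals.empty:
            continue
        starts = np.sort(ivals["start"].to_numpy())
        ends = np.sort(ivals["end"].to_numpy())
        p = sub["pos0"].to_numpy()
        # number of islands starting at/before p vs ending at/before p:
        # unequal counts mean p is inside an island
        n_start = np.searchsorted(starts, p, side="right")
        n_end = np.searchsorted(ends, p, side="right")
        inside = n_start > n_end
        # distance to the closest island edge on either side
        next_start = starts[np.minimum(n_start, len(starts) - 1)]
        d_right = np.where(n_start < len(starts), next_start - p, np.inf)
        prev_end = ends[np.maximum(n_end - 1, 0)]
        d_left = np.where(n_end > 0, p - prev_end + 1, np.inf)
        d = np.minimum(d_right, d_left)
        d[inside] = 0
        dist[sub.index.to_numpy()] = d

    context = np.select(
        [dist == 0, dist <= SHORE_MAX_BP, dist <= SHELF_MAX_BP],
        ["island", "shore", "shelf"], default="inter_cgi")
    return pd.DataFrame({"cgi_context": context,
                         "cgi_distance": dist},
                        index=pd.Index(pos["probe_id"], name="probe_id"))


def annotate_gene(positions: pd.DataFrame,
                  genes: pd.DataFrame) -> pd.DataFrame:
    """Gene context per probe; returns probe_id-indexed frame with
    ``gene_context`` and ``nearest_gene``."""
    pos = _positions_frame(positions)
    context = np.array(["intergenic"] * len(pos), dtype=object)
    nearest = np.array([""] * len(pos), dtype=object)
    for chrom, sub in pos.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        p = sub["pos0"].to_numpy()[:, None]          # probes x 1
        tss = g["tss"].to_numpy()[None, :]
        plus = (g["strand"] == "+").to_numpy()[None, :]
        upstream = np.where(plus, tss - p, p - tss)  # bp upstream of TSS
        in_body = (p >= g["start"].to_numpy()[None, :]) & \
                  (p < g["end"].to_numpy()[None, :])
        is_prom = (upstream >= 1) & (upstream <= PROMOTER_MAX_BP)
        is_prom_plus = (upstream > PROMOTER_MAX_BP) & \
                       (upstream <= PROMOTER_PLUS_MAX_BP)
        tss_gap = np.abs(tss - p)
        gene_ids = g["gene_id"].to_numpy()
        idx = sub.index.to_numpy()
        for row in range(len(p)):
            for mask, label in ((is_prom[row], "promoter"),
                                (is_prom_plus[row], "promoter_plus"),
                                (in_body[row], "gene_body")):
                if mask.any():
                    cand = np.where(mask)[0]
                    best = cand[np.argmin(tss_gap[row][cand])]
                    context[idx[row]] = label
                    nearest[idx[row]] = gene_ids[best]
                    break
            else:
                best = int(np.argmin(tss_gap[row]))
                nearest[idx[row]] = gene_ids[best]
    return pd.DataFrame({"gene_context": context, "nearest_gene": nearest},
                        index=pd.Index(pos["probe_id"], name="probe_id"))


def annotate_contexts(positions: pd.DataFrame, cgi_intervals: pd.DataFrame,
                      genes: pd.DataFrame) -> pd.DataFrame:
    """Both context axes in one probe_id-indexed frame."""
    return annotate_cgi(positions, cgi_intervals).join(
        annotate_gene(positions, genes))


def context_distribution_test(observed: pd.Series,
                              background: pd.Series) -> tuple[float, float]:
    """Pearson χ² goodness-of-fit of observed category counts against the
    background-proportional expectation; df = categories − 1."""
    observed = observed.astype(float)
    background = background.reindex(observed.index).astype(float)
    if observed.sum() == 0:
        raise ValueError("observed counts are all zero")
    bad = (observed > 0) & ~(background > 0)
    if bad.any():
        raise ValueError(
            f"background count zero for observed categories "
            f"{observed.index[bad].tolist()}")
    keep = background > 0
    obs = observed[keep]
    expected = background[keep] / background[keep].sum() * obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = int(keep.sum()) - 1
    p = float(chi2_dist.sf(stat, df)) if df > 0 else 1.0
    return stat, p


def dmr_context_breakdown(member_contexts: pd.DataFrame,
                          axis: str = "cgi_context") -> pd.Series:
    """Fraction of a region's member probes per context class (a region
    inherits every context any member carries)."""
    counts = member_contexts[axis].value_counts()
    return counts / counts.sum()
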