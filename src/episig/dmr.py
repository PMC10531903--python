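"""Differentially methylated region (DMR) calling.

Significant probes (BH-adjusted p below ``sig_alpha``) are chained along
each chromosome while consecutive significant probes lie within
``max_gap`` bp of each other.  Chains with at least ``min_probes``
members and an absolute mean Δβ of at least ``min_mean_delta`` become
candidate regions; each candidate gets Fisher's combined statistic
X² = −2 Σ ln p over its member probes (χ² with 2k df), candidates are
BH-adjusted as a family, and regions below ``region_alpha`` are
reported.

Member p-values entering Fisher's method are the moderated BH-adjusted
values by default (consistent with the "significant probe" definition);
raw p-values can be combined instead via ``use_raw_p``.  Fisher's method
assumes independence, which neighbouring probes violate, so region
p-values are approximate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests


class DataError(ValueError):
    pass


@dataclass
class DMR:
    chrom: str
    start: int              # 0-based half-open, covering member probes
    end: int
    n_probes: int
    mean_delta_beta: float
    fisher_stat: float
    fisher_p: float
    fisher_p_adjusted: float
    member_probe_ids: list[str]


def fisher_combine(p_values: np.ndarray) -> tuple[float, float]:
    """Fisher's method: X² = −2 Σ ln p, p from χ² with 2k df."""
    p = np.clip(np.asarray(p_values, dtype=float), 1e-300, 1.0)
    stat = float(-2.0 * np.log(p).sum())
    return stat, float(chi2.sf(stat, 2 * len(p)))


def call_dmrs(
    stats: pd.DataFrame,
    manifest: pd.DataFrame,
    sig_alpha: float = 0.05,
    max_gap: int = 1000,
    min_probes: int = 5,
    min_mean_delta: float = 0.05,
    region_alpha: float = 0.01,
    use_raw_p: bool = False,
) -> list[DMR]:
    """Call DMRs from the per-probe statistics table.

    ``stats`` must be indexed by probe id with ``p_adjusted``, ``p_value``
    and ``delta_beta`` columns; ``manifest`` supplies chromosome/position
    and must be position-sorted within each chromosome.
    """
    man = manifest.set_index("probe_id")
    missing = stats.index.difference(man.index)
    if len(missing):
        raise DataError(f"{len(missing)} probes missing from manifest")
    man = man.loc[stats.index]
    for chrom, sub in man.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing:
            raise DataError(f"manifest positions not sorted on {chrom}")

    p_col = "p_value" if use_raw_p else "p_adjusted"
    tbl = pd.DataFrame({
        "chrom": man["chrom"],
        "pos": man["pos"],
        "p_adjusted": stats["p_adjusted"],
        "p_member": stats[p_col],
        "delta_beta": stats["delta_beta"],
    }).dropna(subset=["p_adjusted"])

    candidates: list[dict] = []
    sig = tbl[tbl["p_adjusted"] < sig_alpha]
    for chrom, sub in sig.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > max_gap)[0] + 1
        for chunk in np.split(np.arange(len(pos)), breaks):
            if len(chunk) < min_probes:
                continue
            members = sub.iloc[chunk]
            mean_delta = float(members["delta_beta"].mean())
            if abs(mean_delta) < min_mean_delta:
                continue
            stat, p = fisher_combine(members["p_member"].to_numpy())
            candidates.append({
                "chrom": chrom,
                "start": int(members["pos"].min()) - 1,
                "end": int(members["pos"].max()),
                "n_probes": len(members),
                "mean_delta_beta": mean_delta,
                "fisher_stat": stat,
                "fisher_p": p,
                "members": members.index.tolist(),
            })

    if not candidates:
        return []
    adj = multipletests([c["fisher_p"] for c in candidates],
                        method="fdr_bh")[1]
    out = []
    for c, pa in zip(candidates, adj):
        if pa < region_alpha:
            out.append(DMR(
                chrom=c["chrom"], start=c["start"], end=c["end"],
                n_probes=c["n_probes"],
                mean_delta_beta=c["mean_delta_beta"],
                fisher_stat=c["fisher_stat"], fisher_p=c["fisher_p"],
                fisher_p_adjusted=float(pa),
                member_probe_ids=c["members"]))
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end,
        "n_probes": r.n_probes, "mean_delta_beta": r.mean_delta_beta,
        "fisher_stat": r.fisher_stat, "fisher_p": r.fisher_p,
        "fisher_p_adjusted": r.fisher_p_adjusted,
        "member_probe_ids": ",".join(r.member_probe_ids),
    } for r in dmrs])


def write_bed(dmrs: list[DMR], path: str | Path) -> None:
    """BED: chrom, start, end, name, score = −log10 adjusted p (capped)."""
    lines = []
    for i, r in enumerate(dmrs):
        score = min(1000.0, -np.log10(max(r.fisher_p_adjusted, 1e-300)))
        lines.append(f"{r.chrom}\t{r.start}\t{r.end}\tDMR{i + 1}"
                     f"\t{score:.3f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
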