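"""Probe/sample quality control, the beta→M logit transform, and a
PCA-based sample outlier screen.

The filtering contract mirrors standard array practice: samples with more
than 5% detection failures are excluded first, then probes are removed in
a fixed order — detection failure (p > 0.1 in any retained sample), sex
chromosomes, SNP-flagged, cross-reactive/blocklisted — each probe tallied
once under the first reason that triggers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DETECTION_P_MAX = 0.1
SAMPLE_FAIL_FRACTION = 0.05
#: beta values are clamped to this open interval before the plain logit
BETA_CLAMP = 1e-6


class DataError(ValueError):
    """Inconsistent inputs (probes missing from manifest, shape mismatch)."""


@dataclass
class QCReport:
    """Tally of removed probes/samples; probes counted once per first reason."""

    probes_removed: dict[str, int] = field(default_factory=dict)
    samples_removed: list[dict] = field(default_factory=list)
    probes_remaining: int = 0

    def to_dict(self) -> dict:
        return {
            "probes_removed": dict(self.probes_removed),
            "samples_removed": list(self.samples_removed),
            "probes_remaining": int(self.probes_remaining),
        }


def filter_samples(
    detp: pd.DataFrame,
    threshold: float = SAMPLE_FAIL_FRACTION,
    detection_p_max: float = DETECTION_P_MAX,
) -> tuple[list[str], QCReport]:
    """Exclude samples whose fraction of failed probes strictly exceeds
    ``threshold`` (a probe fails in a sample when detection p > 0.1)."""
    if detp.size == 0:
        raise DataError("empty detection-p matrix")
    fail_frac = (detp.to_numpy() > detection_p_max).mean(axis=0)
    kept = [s for s, f in zip(detp.columns, fail_frac) if f <= threshold]
    report = QCReport(
        samples_removed=[
            {"sample_id": s, "failed_fraction": float(f)}
            for s, f in zip(detp.columns, fail_frac) if f > threshold
        ],
        probes_remaining=detp.shape[0],
    )
    return kept, report


def filter_probes(
    beta: pd.DataFrame,
    detp: pd.DataFrame | None,
    manifest: pd.DataFrame,
    blocklists: Iterable[Sequence[str]] = (),
    detection_p_max: float = DETECTION_P_MAX,
) -> tuple[pd.DataFrame, QCReport]:
    """Remove low-quality probes in a fixed, documented order.

    Order: detection failure in >=1 sample of ``beta`` → sex chromosomes →
    SNP-flagged → cross-reactive or blocklisted.  Each probe is counted
    under the first reason that fires.  ``detp`` may be None (no detection
    filtering).  Every probe in ``beta`` must appear in ``manifest``.
    """
    man = manifest.set_index("probe_id")
    missing = beta.index.difference(man.index)
    if len(missing):
        raise DataError(
            f"{len(missing)} probes absent from manifest, e.g. "
            f"{missing[:3].tolist()}")
    man = man.reindex(beta.index)

    n = beta.shape[0]
    removed = np.zeros(n, dtype=bool)
    counts: dict[str, int] = {}

    def _apply(reason: str, mask: np.ndarray) -> None:
        new = mask & ~removed
        counts[reason] = int(new.sum())
        removed[new] = True

    if detp is not None:
        detp = detp.reindex(index=beta.index, columns=beta.columns)
        _apply("detection_p", (detp.to_numpy() > detection_p_max).any(axis=1))
    else:
        counts["detection_p"] = 0
    _apply("sex_chromosome", man["flag_sex_chrom"].to_numpy(dtype=bool))
    _apply("snp", man["flag_snp"].to_numpy(dtype=bool))
    blocked = man["flag_cross_reactive"].to_numpy(dtype=bool).copy()
    for bl in blocklists:
        blocked |= beta.index.isin(list(bl))
    _apply("cross_reactive_or_blocklisted", blocked)

    out = beta.loc[~removed]
    report = QCReport(probes_removed=counts, probes_remaining=out.shape[0])
    return out, report


def beta_to_m(beta: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """M = log2((beta + offset) / (1 - beta + offset)).

    With ``offset == 0`` beta is clamped to [1e-6, 1 - 1e-6] so the plain
    logit stays finite.  Missing values propagate.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    vals = beta.to_numpy(dtype=float)
    if offset == 0:
        vals = np.clip(vals, BETA_CLAMP, 1.0 - BETA_CLAMP)
    with np.errstate(invalid="ignore"):
        m = np.log2((vals + offset) / (1.0 - vals + offset))
    return pd.DataFrame(m, index=beta.index, columns=beta.columns)


def m_to_beta(m: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m` (exact for offset 0 away from clamps)."""
    r = np.power(2.0, m.to_numpy(dtype=float))
    beta = (r * (1.0 + offset) - offset) / (1.0 + r)
    return pd.DataFrame(beta, index=m.index, columns=m.columns)


def pca_outliers(
    m: pd.DataFrame,
    n_components: int = 2,
    z_threshold: float = 3.0,
) -> tuple[list[str], pd.DataFrame]:
    """Flag samples whose scores on the leading principal components are
    extreme under a robust (median/MAD) z-score.

    Returns ``(flagged_sample_ids, scores)`` where ``scores`` has one row
    per sample and columns ``PC1..PCk`` plus matching robust z columns.
    """
    n_samples = m.shape[1]
    if n_samples < 3:
        raise ValueError("need at least 3 samples for the outlier screen")
    if n_samples < n_components:
        raise ValueError("fewer samples than requested components")
    x = m.to_numpy(dtype=float).T          # samples x probes
    x = x - x.mean(axis=0, keepdims=True)
    # SVD-based PCA keeps memory linear in samples^2 via the Gram matrix
    gram = x @ x.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1][:n_components]
    scores = evecs[:, order] * np.sqrt(np.clip(evals[order], 0, None))
    # deterministic sign: largest-|loading| sample positive
    for j in range(scores.shape[1]):
        k = np.argmax(np.abs(scores[:, j]))
        if scores[k, j] < 0:
            scores[:, j] *= -1

    out = pd.DataFrame(
        scores, index=m.columns,
        columns=[f"PC{j + 1}" for j in range(scores.shape[1])])
    flagged: set[str] = set()
    for col in list(out.columns):
        med = out[col].median()
        mad = np.median(np.abs(out[col] - med))
        scale = 1.4826 * mad
        if scale == 0:
            # degenerate spread: fall back to SD, still robust to all-equal
            scale = out[col].std(ddof=1)
        z = (out[col] - med) / scale if scale > 0 else out[col] * 0.0
        out[f"{col}_z"] = z
        flagged.update(out.index[np.abs(z) > z_threshold])
    return sorted(flagged), out
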