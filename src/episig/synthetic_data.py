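"""Synthetic methylation-array cohorts with known ground truth.

Real episignature studies start from normalized beta matrices measured on
Infinium-style arrays, a clinical case series, and a large pool of healthy
controls.  This module fabricates all of those ingredients with the
statistical structure the downstream analysis assumes:

* per-probe baseline methylation drawn from a three-mode Beta mixture
  (unmethylated / intermediate / methylated), mimicking the bimodal
  marginal distribution of array data;
* a case cohort carrying a consistent multi-probe shift ("episignature")
  implanted on the beta scale and truncated to [0, 1];
* blood-cell-composition variation (six cell classes from a Dirichlet)
  that perturbs a probe subset disjoint from the signature, so covariate
  adjustment is testable;
* detection p-values concentrated near zero with a configurable failure
  fraction, exercising the p > 0.1 probe filter;
* a probe manifest with sex-chromosome / SNP / cross-reactive flags and a
  small genome annotation (CpG islands, gene models) populating every
  CGI and gene context class.

Everything is driven by an explicit integer seed; identical seeds yield
identical studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CELL_TYPES = ("CD4T", "CD8T", "NK", "Mono", "Gran", "Bcell")

#: population mean blood-cell proportions (healthy adult, granulocyte-rich)
_CELL_BASELINE = np.array([0.16, 0.09, 0.06, 0.08, 0.54, 0.07])
_CELL_CONCENTRATION = 120.0

#: Beta-mixture baseline modes: (weight, a, b) — means ~0.1 / 0.5 / 0.9
_BASELINE_MODES = ((0.40, 2.0, 18.0), (0.20, 10.0, 10.0), (0.40, 18.0, 2.0))


class SimulationError(ValueError):
    """Raised for infeasible simulation requests."""


# ---------------------------------------------------------------------------
# manifest and genome annotation
# ---------------------------------------------------------------------------

@dataclass
class GenomeAnnotation:
    """CpG islands and gene models on the simulated genome.

    Coordinates are 0-based half-open, BED-style.  ``genes`` carries one row
    per gene with columns ``gene_id, chrom, strand, tss, start, end,
    exon_starts, exon_ends`` (exon bounds as comma-joined strings so the
    table survives a TSV round trip).
    """

    cgi_intervals: pd.DataFrame
    genes: pd.DataFrame

    def validate(self) -> None:
        cgi = self.cgi_intervals
        if (cgi["start"] < 0).any() or (cgi["start"] >= cgi["end"]).any():
            raise SimulationError("CGI intervals must satisfy 0 <= start < end")
        g = self.genes
        bad = (g["tss"] < g["start"]) | (g["tss"] > g["end"])
        if bad.any():
            raise SimulationError("gene TSS must lie within the gene span")


# layout constants for the synthetic genome: one "locus" unit per _LOCUS_BP
# containing a 1 kb CGI and a 10 kb gene, far enough apart that island,
# shore, shelf, inter-CGI, promoter, promoter+, gene-body and intergenic
# contexts all exist.
_LOCUS_BP = 40_000
_CGI_OFFSET = 10_000
_CGI_LEN = 1_000
_GENE_OFFSET = 20_000
_GENE_LEN = 10_000


def simulate_manifest(
    n_probes: int,
    n_chroms: int = 3,
    seed: int = 0,
    sex_chrom_fraction: float = 0.02,
    flag_snp_rate: float = 0.01,
    flag_cross_reactive_rate: float = 0.01,
) -> tuple[pd.DataFrame, GenomeAnnotation]:
    """Simulate an EPIC-like probe manifest plus matching genome annotation.

    Parameters
    ----------
    n_probes
        Total probe count (>= 100).
    n_chroms
        Number of autosomes; chrX and chrY are always appended with a small
        probe fraction so the sex-chromosome filter has work to do.
    seed
        Seed for all randomness.

    Returns
    -------
    manifest : pandas.DataFrame
        Columns ``probe_id, chrom, pos, flag_sex_chrom, flag_snp,
        flag_cross_reactive``; ``pos`` is 1-based; rows sorted by
        (chromosome, position); ``probe_id`` unique.
    annotation : GenomeAnnotation
    """
    if n_probes < 100:
        raise SimulationError(f"n_probes must be >= 100, got {n_probes}")
    if n_chroms < 1:
        raise SimulationError(f"n_chroms must be >= 1, got {n_chroms}")
    rng = np.random.default_rng(seed)

    autosomes = [f"chr{i}" for i in range(1, n_chroms + 1)]
    n_sex = max(2, int(round(n_probes * sex_chrom_fraction)))
    n_y = max(1, n_sex // 4)
    n_x = n_sex - n_y
    n_auto = n_probes - n_sex
    per_chrom = {c: n_auto // n_chroms for c in autosomes}
    per_chrom[autosomes[0]] += n_auto - sum(per_chrom.values())
    per_chrom["chrX"] = n_x
    per_chrom["chrY"] = n_y

    cgi_rows, gene_rows = [], []
    chrom_col, pos_col = [], []
    gene_counter = 0
    for chrom in autosomes + ["chrX", "chrY"]:
        n_c = per_chrom[chrom]
        n_loci = max(2, n_c // 60)
        chrom_len = n_loci * _LOCUS_BP
        positions: list[int] = []
        for k in range(n_loci):
            base = k * _LOCUS_BP
            cgi_s = base + _CGI_OFFSET
            cgi_e = cgi_s + _CGI_LEN
            cgi_rows.append((chrom, cgi_s, cgi_e))
            strand = "+" if k % 2 == 0 else "-"
            g_s = base + _GENE_OFFSET
            g_e = g_s + _GENE_LEN
            tss = g_s if strand == "+" else g_e
            n_ex = 3
            ex_len = _GENE_LEN // (2 * n_ex)
            ex_s = [g_s + 2 * i * ex_len for i in range(n_ex)]
            ex_e = [s + ex_len for s in ex_s]
            gene_rows.append(
                (f"G{gene_counter:05d}", chrom, strand, tss, g_s, g_e,
                 ",".join(map(str, ex_s)), ",".join(map(str, ex_e))))
            gene_counter += 1
            if chrom not in ("chrX", "chrY"):
                # guarantee every context class at the first loci of each
                # autosome: island / shore / shelf / inter-CGI and
                # promoter / promoter+ / gene body / intergenic
                promoter_pos = tss - 500 if strand == "+" else tss + 500
                promoter_plus_pos = tss - 3_000 if strand == "+" else tss + 3_000
                positions.extend([
                    cgi_s + _CGI_LEN // 2,   # island
                    cgi_e + 1_500,           # shore
                    cgi_e + 3_000,           # shelf
                    base + 2_000,            # inter-CGI and intergenic
                    promoter_pos,
                    promoter_plus_pos,
                    g_s + _GENE_LEN // 2,    # gene body
                ])
        # keep the guaranteed context probes; oversample random fill so
        # position collisions cannot shrink the final count
        guaranteed = sorted(set(int(p) for p in positions if p >= 1))
        n_rand = max(0, n_c - len(guaranteed))
        seen = set(guaranteed)
        fill: list[int] = []
        for p in rng.integers(1, chrom_len, size=2 * n_rand + 16):
            p = int(p)
            if p not in seen:
                seen.add(p)
                fill.append(p)
            if len(fill) == n_rand:
                break
        positions = sorted(set(guaranteed) | set(fill))
        if len(positions) > n_c:
            positions = positions[:n_c]
        chrom_col.extend([chrom] * len(positions))
        pos_col.extend(positions)

    manifest = pd.DataFrame({
        "chrom": chrom_col,
        # positions are 1-based single CpG sites
        "pos": np.asarray(pos_col, dtype=np.int64) + 1,
    })
    manifest["probe_id"] = [f"cg{i:08d}" for i in range(len(manifest))]
    manifest["flag_sex_chrom"] = manifest["chrom"].isin(["chrX", "chrY"])
    manifest["flag_snp"] = rng.random(len(manifest)) < flag_snp_rate
    manifest["flag_cross_reactive"] = (
        rng.random(len(manifest)) < flag_cross_reactive_rate
    )
    manifest = manifest[
        ["probe_id", "chrom", "pos", "flag_sex_chrom", "flag_snp",
         "flag_cross_reactive"]
    ].reset_index(drop=True)

    annotation = GenomeAnnotation(
        cgi_intervals=pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"]),
        genes=pd.DataFrame(
            gene_rows,
            columns=["gene_id", "chrom", "strand", "tss", "start", "end",
                     "exon_starts", "exon_ends"]),
    )
    annotation.validate()
    return manifest, annotation


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SignatureSpec:
    """Description of the implanted episignature.

    ``delta_beta`` is the mean beta-scale shift in cases; its sign is forced
    to agree with ``direction`` (hypo => negative, hyper => positive, mixed
    => per-probe random sign).  ``effect_sd`` is the between-probe standard
    deviation of the shift.
    """

    n_signature_probes: int
    delta_beta: float = -0.10
    effect_sd: float = 0.02
    direction: str = "hypo"

    def __post_init__(self) -> None:
        if abs(self.delta_beta) > 0.5:
            raise SimulationError("|delta_beta| must be <= 0.5")
        if self.direction not in ("hypo", "hyper", "mixed"):
            raise SimulationError(f"unknown direction {self.direction!r}")
        if self.n_signature_probes < 0:
            raise SimulationError("n_signature_probes must be >= 0")


@dataclass
class SimulatedStudy:
    """One simulated case/control methylation study with recorded truth."""

    beta: pd.DataFrame
    detp: pd.DataFrame
    samples: pd.DataFrame
    manifest: pd.DataFrame
    annotation: GenomeAnnotation
    truth_signature: list[str] = field(default_factory=list)
    truth_confounded: list[str] = field(default_factory=list)

    @property
    def case_ids(self) -> list[str]:
        return self.samples.loc[self.samples["group"] == "case",
                                "sample_id"].tolist()

    @property
    def control_pool_ids(self) -> list[str]:
        return self.samples.loc[self.samples["group"] == "control_pool",
                                "sample_id"].tolist()

    def write(self, out_dir: str | Path) -> None:
        """Write all study tables as plain text under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.beta.to_csv(out / "beta.tsv", sep="\t")
        self.detp.to_csv(out / "detp.tsv", sep="\t")
        self.samples.to_csv(out / "samples.csv", index=False)
        self.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        self.annotation.cgi_intervals.to_csv(
            out / "cgi.tsv", sep="\t", index=False)
        self.annotation.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump({"signature": self.truth_signature,
                       "confounded": self.truth_confounded}, fh, indent=1)


def _draw_baselines(rng: np.random.Generator, n: int) -> np.ndarray:
    """Per-probe baseline means from the three-mode Beta mixture."""
    weights = np.array([m[0] for m in _BASELINE_MODES])
    modes = rng.choice(len(_BASELINE_MODES), size=n, p=weights / weights.sum())
    out = np.empty(n)
    for i, (_, a, b) in enumerate(_BASELINE_MODES):
        sel = modes == i
        out[sel] = rng.beta(a, b, size=sel.sum())
    return np.clip(out, 0.01, 0.99)


def _expressible_baselines(rng: np.random.Generator, n: int,
                           signs: np.ndarray) -> np.ndarray:
    """Baselines for implanted probes, kept away from the bound the shift
    points at so the implanted effect is expressed without truncation."""
    out = np.empty(n)
    hypo = signs < 0
    out[hypo] = rng.beta(14, 6, size=hypo.sum())      # mean ~0.7
    out[~hypo] = rng.beta(6, 14, size=(~hypo).sum())  # mean ~0.3
    return np.clip(out, 0.15, 0.85)


def simulate_cohort(
    manifest: pd.DataFrame,
    n_cases: int,
    n_control_pool: int,
    spec: SignatureSpec,
    confound_strength: float = 0.3,
    seed: int = 0,
    annotation: GenomeAnnotation | None = None,
    signature_probes: Sequence[str] | None = None,
    n_confound_probes: int | None = None,
    detp_fail_fraction: float = 5e-4,
) -> SimulatedStudy:
    """Simulate one case cohort plus a matched-control pool.

    Per-probe baselines come from a Beta mixture; per-sample beta values are
    Beta-distributed around the baseline with probe-specific precision.
    Signature probes (chosen at random among unflagged autosomal probes, or
    given explicitly via ``signature_probes``) are shifted in cases by
    ``spec.delta_beta`` plus between-probe noise and truncated to [0, 1].
    A disjoint probe subset responds linearly to the granulocyte fraction,
    and case cell composition is tilted by ``confound_strength``, creating
    the cell-composition confounding the linear model must absorb.

    Ages/sexes are assigned so every case has at least five same-sex,
    similar-age pool controls (required by 1:5 matching downstream).
    """
    if n_cases < 2:
        raise SimulationError("n_cases must be >= 2")
    if n_control_pool < 5 * n_cases:
        raise SimulationError(
            f"control pool of {n_control_pool} cannot supply 5 matched "
            f"controls per case for {n_cases} cases")
    rng = np.random.default_rng(seed)
    probe_ids = manifest["probe_id"].to_numpy()
    n_probes = len(probe_ids)
    if spec.n_signature_probes > n_probes:
        raise SimulationError("more signature probes than probes")

    flagged = (manifest["flag_sex_chrom"] | manifest["flag_snp"]
               | manifest["flag_cross_reactive"]).to_numpy()
    eligible = np.where(~flagged)[0]

    # --- truth sets -------------------------------------------------------
    if signature_probes is not None:
        sig_idx = manifest.index[
            manifest["probe_id"].isin(list(signature_probes))].to_numpy()
        if len(sig_idx) != len(set(signature_probes)):
            raise SimulationError("signature_probes not all in manifest")
        if flagged[sig_idx].any():
            raise SimulationError("explicit signature probes carry QC flags")
    else:
        sig_idx = rng.choice(eligible, size=spec.n_signature_probes,
                             replace=False)
    if n_confound_probes is None:
        n_confound_probes = min(200, n_probes // 25)
    conf_pool = np.setdiff1d(eligible, sig_idx)
    conf_idx = rng.choice(conf_pool, size=min(n_confound_probes,
                                              len(conf_pool)), replace=False)

    # --- sample sheet -----------------------------------------------------
    n_total = n_cases + n_control_pool
    case_ids = [f"case_{i:02d}" for i in range(n_cases)]
    pool_ids = [f"ctrl_{i:03d}" for i in range(n_control_pool)]
    case_age = rng.uniform(2, 45, size=n_cases)
    case_sex = rng.choice(["M", "F"], size=n_cases)
    pool_age = np.empty(n_control_pool)
    pool_sex = np.empty(n_control_pool, dtype=object)
    # guarantee >=5 compatible controls per case, then fill the rest freely
    slot = 0
    for i in range(n_cases):
        for _ in range(5):
            pool_age[slot] = max(0.5, case_age[i] + rng.normal(0, 2.0))
            pool_sex[slot] = case_sex[i]
            slot += 1
    pool_age[slot:] = rng.uniform(2, 70, size=n_control_pool - slot)
    pool_sex[slot:] = rng.choice(["M", "F"], size=n_control_pool - slot)

    group = np.array(["case"] * n_cases + ["control_pool"] * n_control_pool)
    is_case = group == "case"

    # cell composition: Dirichlet around the blood baseline; case draws are
    # tilted toward granulocytes in proportion to confound_strength
    shift = np.array([-0.06, -0.03, 0.0, 0.0, 0.12, -0.03])
    alpha_ctrl = _CELL_BASELINE * _CELL_CONCENTRATION
    alpha_case = np.clip(_CELL_BASELINE + confound_strength * shift,
                         0.01, None) * _CELL_CONCENTRATION
    cells = np.empty((n_total, 6))
    cells[is_case] = rng.dirichlet(alpha_case, size=n_cases)
    cells[~is_case] = rng.dirichlet(alpha_ctrl, size=n_control_pool)

    samples = pd.DataFrame({
        "sample_id": case_ids + pool_ids,
        "group": group,
        "age": np.concatenate([case_age, pool_age]).round(1),
        "sex": np.concatenate([case_sex, pool_sex]),
        "array_type": "EPIC",
        "batch": "batch1",
    })
    for j, ct in enumerate(CELL_TYPES):
        samples[ct] = cells[:, j]

    # --- beta matrix ------------------------------------------------------
    baseline = _draw_baselines(rng, n_probes)
    # per-probe effect sizes (0 off-signature)
    effect = np.zeros(n_probes)
    if len(sig_idx) and spec.delta_beta != 0:
        mag = abs(spec.delta_beta) + rng.normal(0, spec.effect_sd,
                                                size=len(sig_idx))
        if spec.direction == "hypo":
            signs = -np.ones(len(sig_idx))
        elif spec.direction == "hyper":
            signs = np.ones(len(sig_idx))
        else:
            signs = rng.choice([-1.0, 1.0], size=len(sig_idx))
        effect[sig_idx] = signs * np.abs(mag)
        baseline[sig_idx] = _expressible_baselines(rng, len(sig_idx), signs)
    # confounded probes are cell-composition responsive; keep them at
    # intermediate methylation so the linear response is not truncated
    gamma = np.zeros(n_probes)
    if len(conf_idx) and confound_strength >= 0:
        gamma[conf_idx] = rng.uniform(0.5, 1.0, size=len(conf_idx)) * \
            rng.choice([-1.0, 1.0], size=len(conf_idx))
        baseline[conf_idx] = np.clip(rng.beta(10, 10, size=len(conf_idx)),
                                     0.2, 0.8)

    precision = np.exp(rng.normal(np.log(150.0), 0.3, size=n_probes))
    mean = np.tile(baseline, (n_total, 1)).T          # probes x samples
    mean[:, is_case] += effect[:, None]
    gran_dev = cells[:, CELL_TYPES.index("Gran")] - _CELL_BASELINE[4]
    mean += gamma[:, None] * gran_dev[None, :]
    mean = np.clip(mean, 0.005, 0.995)
    a = mean * precision[:, None]
    b = (1.0 - mean) * precision[:, None]
    beta_vals = rng.beta(a, b)

    detp_vals = rng.uniform(1e-6, 0.01, size=beta_vals.shape)
    if detp_fail_fraction > 0:
        fail = rng.random(beta_vals.shape) < detp_fail_fraction
        detp_vals[fail] = rng.uniform(0.11, 0.9, size=fail.sum())

    all_ids = case_ids + pool_ids
    beta = pd.DataFrame(beta_vals, index=probe_ids, columns=all_ids)
    beta.index.name = "probe_id"
    detp = pd.DataFrame(detp_vals, index=probe_ids, columns=all_ids)
    detp.index.name = "probe_id"

    return SimulatedStudy(
        beta=beta, detp=detp, samples=samples, manifest=manifest,
        annotation=annotation
        if annotation is not None
        else GenomeAnnotation(pd.DataFrame(columns=["chrom", "start", "end"]),
                              pd.DataFrame(columns=["gene_id", "chrom",
                                                    "strand", "tss", "start",
                                                    "end", "exon_starts",
                                                    "exon_ends"])),
        truth_signature=probe_ids[np.sort(sig_idx)].tolist(),
        truth_confounded=probe_ids[np.sort(conf_idx)].tolist(),
    )


def find_probe_run(manifest: pd.DataFrame, n: int,
                   max_gap: int = 1000) -> list[str]:
    """First run of ``n`` consecutive unflagged autosomal probes whose
    successive gaps are all <= ``max_gap`` bp (handy for implanting a
    region-shaped signature)."""
    ok = ~(manifest["flag_sex_chrom"] | manifest["flag_snp"]
           | manifest["flag_cross_reactive"])
    for chrom, sub in manifest[ok].groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        ids = sub["probe_id"].to_numpy()
        run_start = 0
        for i in range(1, len(pos)):
            if pos[i] - pos[i - 1] > max_gap:
                run_start = i
            if i - run_start + 1 >= n:
                return ids[i - n + 1:i + 1].tolist()
    raise SimulationError(
        f"no run of {n} probes with gaps <= {max_gap} bp found")


# ---------------------------------------------------------------------------
# multi-cohort disorder panel
# ---------------------------------------------------------------------------

@dataclass
class OverlapPlan:
    """Requested truth-set sizes and exact pairwise sharing between cohorts.

    ``shared`` maps unordered cohort-id pairs to the number of probes their
    truth sets must have in common.  Triple-wise sharing is not modelled:
    shared blocks for distinct pairs are disjoint, so realized pairwise
    intersections equal the plan exactly.
    """

    sizes: dict[str, int]
    shared: dict[tuple[str, str], int] = field(default_factory=dict)

    def normalized_shared(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for (a, b), k in self.shared.items():
            if a == b:
                raise SimulationError("self-pairs not allowed in overlap plan")
            key = (a, b) if a < b else (b, a)
            out[key] = out.get(key, 0) + k
        return out

    def validate(self) -> None:
        shared = self.normalized_shared()
        for (a, b), k in shared.items():
            for c in (a, b):
                if c not in self.sizes:
                    raise SimulationError(f"unknown cohort {c!r} in plan")
            if k < 0:
                raise SimulationError("negative shared count")
        for c, size in self.sizes.items():
            committed = sum(k for (a, b), k in shared.items() if c in (a, b))
            if committed > size:
                raise SimulationError(
                    f"cohort {c!r}: shared probes ({committed}) exceed its "
                    f"truth-set size ({size})")


def simulate_disorder_panel(
    manifest: pd.DataFrame,
    plan: OverlapPlan,
    seed: int = 0,
    n_cases: int = 6,
    n_control_pool: int = 30,
    delta_beta: float = -0.10,
    with_studies: bool = True,
    annotation: GenomeAnnotation | None = None,
) -> tuple[dict[str, list[str]], dict[str, SimulatedStudy]]:
    """Build several disorder cohorts whose truth-set intersections realize
    ``plan`` exactly.

    Returns ``(truth_sets, studies)``; ``studies`` is empty when
    ``with_studies`` is false (truth sets alone are enough for overlap /
    tree analyses on known signatures).
    """
    plan.validate()
    shared = plan.normalized_shared()
    rng = np.random.default_rng(seed)
    flagged = (manifest["flag_sex_chrom"] | manifest["flag_snp"]
               | manifest["flag_cross_reactive"]).to_numpy()
    eligible = manifest.loc[~flagged, "probe_id"].to_numpy().copy()
    rng.shuffle(eligible)
    need = sum(plan.sizes.values()) - sum(shared.values())
    if need > len(eligible):
        raise SimulationError(
            f"plan needs {need} distinct probes but only {len(eligible)} "
            "unflagged probes exist")

    cursor = 0
    truth: dict[str, set[str]] = {c: set() for c in plan.sizes}
    for (a, b), k in sorted(shared.items()):
        block = eligible[cursor:cursor + k]
        cursor += k
        truth[a].update(block)
        truth[b].update(block)
    for c in sorted(plan.sizes):
        deficit = plan.sizes[c] - len(truth[c])
        block = eligible[cursor:cursor + deficit]
        cursor += deficit
        truth[c].update(block)

    truth_lists = {c: sorted(s) for c, s in truth.items()}
    studies: dict[str, SimulatedStudy] = {}
    if with_studies:
        for i, c in enumerate(sorted(plan.sizes)):
            studies[c] = simulate_cohort(
                manifest, n_cases, n_control_pool,
                SignatureSpec(n_signature_probes=len(truth_lists[c]),
                              delta_beta=delta_beta),
                confound_strength=0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
                annotation=annotation,
                signature_probes=truth_lists[c],
            )
    return truth_lists, studies


def simulate_clinical_table(
    n_cases: int,
    prevalences: dict[str, float],
    seed: int = 0,
    missing_rate: float = 0.0,
):
    """Random clinical +/- feature matrix with given per-feature prevalence."""
    from .clinical_summary import ClinicalTable

    for f, p in prevalences.items():
        if not 0.0 <= p <= 1.0:
            raise SimulationError(f"prevalence for {f!r} outside [0,1]")
    rng = np.random.default_rng(seed)
    cases = [f"case_{i:02d}" for i in range(n_cases)]
    entries = {}
    for feat, p in prevalences.items():
        row = np.where(rng.random(n_cases) < p, "+", "-")
        if missing_rate > 0:
            row = np.where(rng.random(n_cases) < missing_rate, "", row)
        entries[feat] = row
    frame = pd.DataFrame(entries, index=cases).T
    frame.index.name = "feature"
    return ClinicalTable(frame)
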