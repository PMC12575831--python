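"""Ground-truthed synthetic inputs for every pipeline stage.

Three forward models, each the exact inverse of the analysis stage that
consumes it:

* pileups — deletion counts at true Ψ fractions: in a BS-treated library
  a read deletes at the site with probability f*c + (1-f)*e_t (conversion
  rate c, background error e_t); input libraries delete at e_i. Depth is
  Poisson (negative binomial behind an overdispersion knob). Decoy sites
  (non-U reference, low depth, elevated input background) exercise the
  filter cascade.
* coverage — per-gene promoter sums ~ Poisson(lambda) and body sums
  ~ Poisson(lambda * rho) deposited uniformly over the exact PRR windows,
  so window coverage recovers the drawn counts and the PRR estimates rho.
* Ct quartets — the qPCR forward model ct_bs_psi = a' - log2(1-f) + eps
  with matched probe baselines, which the ddCt estimator inverts exactly
  at zero noise.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bihind import CtQuartet
from .core_io import CoverageTrack, GeneModel
from .kas_prr import build_windows


# ---------------------------------------------------------------------------
# Pileup simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PileupSimSpec:
    """Forward model for deletion-signature pileups.

    ``true_fraction`` may be a scalar (shared by all sites) or one value
    per site. Decoy counts are appended after the ``n_sites`` true sites.
    """

    n_sites: int = 100
    true_fraction: float | Sequence[float] = 0.5
    depth_mean: float = 100.0
    conversion_rate: float = 1.0
    treated_background: float = 0.002
    input_background: float = 0.002
    n_treated: int = 3
    n_input: int = 3
    seed: int = 0
    chrom: str = "chrSim"
    start_pos0: int = 1000
    spacing: int = 10
    strand: str = "+"
    nb_size: float | None = None       # overdispersed depth when set
    decoy_non_u: int = 0
    decoy_low_depth: int = 0
    decoy_high_input: int = 0
    high_input_background: float = 0.05
    low_depth_mean: float = 10.0
    library_prefix: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.conversion_rate <= 1):
            raise ValueError("conversion_rate must be in (0, 1]")
        if self.treated_background >= 0.05 or self.input_background >= 0.05:
            raise ValueError("background deletion rates must be < 0.05")
        if self.conversion_rate <= self.treated_background:
            raise ValueError("conversion_rate must exceed treated background")
        fs = np.atleast_1d(np.asarray(self.true_fraction, float))
        if ((fs < 0) | (fs > 1)).any():
            raise ValueError("true fractions must lie in [0, 1]")

    def fractions(self) -> np.ndarray:
        fs = np.atleast_1d(np.asarray(self.true_fraction, float))
        if fs.size == 1:
            return np.full(self.n_sites, float(fs[0]))
        if fs.size != self.n_sites:
            raise ValueError("true_fraction length must match n_sites")
        return fs


def _draw_depth(rng: np.random.Generator, mean: float, size, nb_size: float | None):
    if nb_size is None:
        return rng.poisson(mean, size=size)
    p = nb_size / (nb_size + mean)
    return rng.negative_binomial(nb_size, p, size=size)


def simulate_pileups(spec: PileupSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a SiteCounts table and its truth table.

    Returns (counts, truth): counts has the internal pileup schema
    (chrom, pos0, ref_base, depth, del_count, library_id) covering
    ``n_treated`` treated and ``n_input`` input libraries; truth records
    per site the position, strand, reference base, true fraction and
    decoy class ('' for genuine Ψ sites).
    """
    rng = np.random.default_rng(spec.seed)
    u_base = "T" if spec.strand == "+" else "A"

    fractions = list(spec.fractions())
    classes = [""] * spec.n_sites
    depth_means = [spec.depth_mean] * spec.n_sites
    input_bgs = [spec.input_background] * spec.n_sites
    ref_bases = [u_base] * spec.n_sites

    for _ in range(spec.decoy_non_u):
        fractions.append(0.5)
        classes.append("non_u")
        depth_means.append(spec.depth_mean)
        input_bgs.append(spec.input_background)
        ref_bases.append("G")
    for _ in range(spec.decoy_low_depth):
        fractions.append(0.5)
        classes.append("low_depth")
        depth_means.append(spec.low_depth_mean)
        input_bgs.append(spec.input_background)
        ref_bases.append(u_base)
    for _ in range(spec.decoy_high_input):
        fractions.append(0.5)
        classes.append("high_input")
        depth_means.append(spec.depth_mean)
        input_bgs.append(spec.high_input_background)
        ref_bases.append(u_base)

    n_total = len(fractions)
    positions = spec.start_pos0 + spec.spacing * np.arange(n_total)
    fr = np.asarray(fractions)
    p_treated = fr * spec.conversion_rate + (1 - fr) * spec.treated_background

    rows = []
    for j in range(spec.n_treated):
        lib = f"{spec.library_prefix}bs_{j + 1}"
        depth = np.array([_draw_depth(rng, m, None, spec.nb_size) for m in depth_means])
        dels = rng.binomial(depth, p_treated)
        for i in range(n_total):
            rows.append((spec.chrom, int(positions[i]), ref_bases[i],
                         int(depth[i]), int(dels[i]), lib))
    for j in range(spec.n_input):
        lib = f"{spec.library_prefix}in_{j + 1}"
        depth = np.array([_draw_depth(rng, m, None, spec.nb_size) for m in depth_means])
        dels = rng.binomial(depth, np.asarray(input_bgs))
        for i in range(n_total):
            rows.append((spec.chrom, int(positions[i]), ref_bases[i],
                         int(depth[i]), int(dels[i]), lib))

    counts = pd.DataFrame(
        rows, columns=["chrom", "pos0", "ref_base", "depth", "del_count", "library_id"]
    )
    truth = pd.DataFrame(
        {
            "chrom": spec.chrom,
            "pos0": positions,
            "strand": spec.strand,
            "ref_base": ref_bases,
            "true_fraction": fractions,
            "decoy_class": classes,
        }
    )
    return counts, truth


def write_pileup_tsv(counts: pd.DataFrame, path) -> None:
    """Write the internal counts frame in the 1-based on-disk pileup dialect."""
    out = counts.copy()
    out["pos"] = out["pos0"] + 1
    out = out[["chrom", "pos", "ref_base", "depth", "del_count", "library_id"]]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Coverage simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageSimSpec:
    """Forward model for per-gene promoter/body coverage.

    ``true_prr`` is the body/promoter ratio rho, scalar or per gene;
    ``prr_log_sigma`` adds log-normal gene-to-gene spread. Condition B
    multiplies rho by ``condition_effect`` for a ``fraction_affected``
    share of genes.
    """

    n_genes: int = 2000
    lambda_promoter: float = 100.0
    true_prr: float | Sequence[float] = 1.0
    prr_log_sigma: float = 0.0
    condition_effect: float = 1.0
    fraction_affected: float = 1.0
    seed: int = 0
    chrom: str = "chrP"
    gene_length: int = 2500
    spacing: int = 6000
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        if self.lambda_promoter <= 0:
            raise ValueError("lambda_promoter must be positive")
        if not (0 <= self.fraction_affected <= 1):
            raise ValueError("fraction_affected must be in [0, 1]")

    def required_length(self) -> int:
        return 3000 + self.n_genes * self.spacing + 3000


def _layout_genes(spec: CoverageSimSpec) -> list[GeneModel]:
    if spec.chrom_length is not None and spec.chrom_length < spec.required_length():
        raise ValueError(
            f"{spec.n_genes} genes at spacing {spec.spacing} need "
            f"{spec.required_length()} bp; chromosome is {spec.chrom_length}"
        )
    models = []
    for i in range(spec.n_genes):
        block = 3000 + i * spec.spacing
        if i % 2 == 0:
            models.append(GeneModel(f"g{i:05d}", spec.chrom, "+",
                                    block, block + spec.gene_length - 1, "protein_coding"))
        else:
            models.append(GeneModel(f"g{i:05d}", spec.chrom, "-",
                                    block + spec.gene_length - 1, block, "protein_coding"))
    return models


def simulate_window_counts(
    spec: CoverageSimSpec,
) -> tuple[pd.DataFrame, list[GeneModel]]:
    """Draw promoter/body sums per gene for both conditions.

    Returns a truth frame with columns gene_id, strand, true_prr_a,
    true_prr_b, affected, prom_a, body_a, prom_b, body_b, and the gene
    models. The sums are what uniform deposition over the exact windows
    yields, so this is the count-level equivalent of the track route.
    """
    rng = np.random.default_rng(spec.seed)
    models = _layout_genes(spec)
    rho = np.atleast_1d(np.asarray(spec.true_prr, float))
    rho = np.full(spec.n_genes, rho[0]) if rho.size == 1 else rho.astype(float)
    if rho.size != spec.n_genes:
        raise ValueError("true_prr length must match n_genes")
    if spec.prr_log_sigma > 0:
        rho = rho * np.exp(rng.normal(0.0, spec.prr_log_sigma, spec.n_genes))
    affected = rng.random(spec.n_genes) < spec.fraction_affected
    rho_b = np.where(affected, rho * spec.condition_effect, rho)

    lam = spec.lambda_promoter
    prom_a = rng.poisson(lam, spec.n_genes)
    body_a = rng.poisson(lam * rho, spec.n_genes)
    prom_b = rng.poisson(lam, spec.n_genes)
    body_b = rng.poisson(lam * rho_b, spec.n_genes)

    truth = pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in models],
            "strand": [m.strand for m in models],
            "true_prr_a": rho,
            "true_prr_b": rho_b,
            "affected": affected,
            "prom_a": prom_a,
            "body_a": body_a,
            "prom_b": prom_b,
            "body_b": body_b,
        }
    )
    return truth, models


def simulate_coverage(
    spec: CoverageSimSpec,
) -> tuple[dict[str, CoverageTrack], list[GeneModel], pd.DataFrame]:
    """Build per-condition coverage tracks realising the drawn window sums.

    Each gene's promoter sum is spread uniformly over its 400-bp promoter
    window and the body sum over its 1700-bp body window, so integrating
    the track over the analysis windows recovers the Poisson draws.
    Returns ({'A': track, 'B': track}, gene models, truth table).
    """
    truth, models = simulate_window_counts(spec)
    windows = {w.gene_id: w for w in build_windows(models)}
    tracks = {"A": CoverageTrack(), "B": CoverageTrack()}
    for row in truth.itertuples(index=False):
        w = windows[row.gene_id]
        for cond, prom, body in (("A", row.prom_a, row.body_a), ("B", row.prom_b, row.body_b)):
            if prom > 0:
                tracks[cond].add(w.promoter.chrom, w.promoter.start, w.promoter.end,
                                 prom / w.promoter.width)
            if body > 0:
                tracks[cond].add(w.body.chrom, w.body.start, w.body.end,
                                 body / w.body.width)
    return tracks, models, truth


# ---------------------------------------------------------------------------
# Ct quartet simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CtSimSpec:
    """Forward model for BIHIND-qPCR Ct quartets at true fraction f.

    Baselines satisfy the matched-probe constraint: the untreated probe
    offset (a - b) is reproduced in the BS-treated channels, so ddCt at
    zero noise is exactly -log2(1 - f). Gaussian noise of sd
    ``ct_noise_sd`` is added independently to each of the four Ct values.
    """

    true_fraction: float = 0.5
    baseline_unt_psi: float = 20.0
    baseline_unt_u: float = 20.5
    baseline_bs_u: float = 22.0
    ct_noise_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0
    sample_label: str = "sample"

    def __post_init__(self) -> None:
        if not (0 <= self.true_fraction < 1):
            raise ValueError("true_fraction must be in [0, 1); use 1 - 1e-9 near saturation")
        if self.ct_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def simulate_ct(spec: CtSimSpec) -> list[CtQuartet]:
    rng = np.random.default_rng(spec.seed)
    a = spec.baseline_unt_psi
    b = spec.baseline_unt_u
    b2 = spec.baseline_bs_u
    a2 = b2 + (a - b)                     # matched probe offset
    shift = -math.log2(1.0 - spec.true_fraction)
    quartets = []
    for j in range(spec.n_replicates):
        eps = rng.normal(0.0, spec.ct_noise_sd, 4) if spec.ct_noise_sd > 0 else np.zeros(4)
        quartets.append(
            CtQuartet(
                ct_bs_psi=a2 + shift + eps[0],
                ct_bs_u=b2 + eps[1],
                ct_unt_psi=a + eps[2],
                ct_unt_u=b + eps[3],
                replicate_id=f"rep{j + 1}",
                sample_label=spec.sample_label,
            )
        )
    return quartets


def write_ct_tsv(quartets: Sequence[CtQuartet], path) -> None:
    pd.DataFrame(
        {
            "sample_label": [q.sample_label for q in quartets],
            "replicate_id": [q.replicate_id for q in quartets],
            "ct_bs_psi": [f"{q.ct_bs_psi:.6f}" for q in quartets],
            "ct_bs_u": [f"{q.ct_bs_u:.6f}" for q in quartets],
            "ct_unt_psi": [f"{q.ct_unt_psi:.6f}" for q in quartets],
            "ct_unt_u": [f"{q.ct_unt_u:.6f}" for q in quartets],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Complete fixture
# ---------------------------------------------------------------------------

_FIXTURE_GENES = [
    # (gene_id, biotype, strand, start, end)  0-based inclusive span
    ("tRNA-1", "tRNA", "+", 1000, 1999),
    ("snRNA-1", "snRNA", "+", 3000, 3999),
    ("lncRNA-1", "lncRNA", "-", 5000, 5999),
    ("mRNA-1", "protein_coding", "+", 7000, 8999),
    ("snRNA-2", "snRNA", "-", 10000, 10999),
    ("mRNA-2", "protein_coding", "-", 12000, 13999),
]
_SITES_PER_GENE = [8, 8, 8, 8, 4, 4]
_FIXTURE_CHROM = "chrS"
_FIXTURE_LEN = 20000


def _plant_context(seq: list[str], pos: int, strand: str, r_base: str) -> None:
    """Write a UGUAR context (DNA TGTAR) with the U at ``pos``."""
    motif = "TGTA" + r_base
    if strand == "+":
        for k, base in enumerate(motif):
            seq[pos - 2 + k] = base
    else:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(motif))
        for k, base in enumerate(rc):
            seq[pos - 2 + k] = base


def make_fixture(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write a complete small fixture a full pipeline run can consume.

    Contents: a toy genome FASTA with planted UGUAR contexts, a GTF with
    mixed-biotype genes, per-library pileup TSVs for two conditions
    (3 BS-treated + 3 input each; condition B has reduced fractions at a
    subset of sites), two KAS-style bedGraph tracks with a gene-model TSV,
    a BIHIND Ct table, and truth tables for each stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}

    # --- genome with planted sites -------------------------------------
    seq = list(rng.choice(list("ACGT"), size=_FIXTURE_LEN))
    site_rows = []
    idx = 0
    for (gene_id, biotype, strand, gstart, gend), n_sites in zip(_FIXTURE_GENES, _SITES_PER_GENE):
        for k in range(n_sites):
            pos = gstart + 120 + 40 * k
            u_base = "T" if strand == "+" else "A"
            if idx % 2 == 0:
                r_base = "A" if (idx // 2) % 2 == 0 else "G"
                _plant_context(seq, pos, strand, r_base)
                motif_planted = True
            else:
                seq[pos] = u_base
                # deterministically break the consensus at the G position
                if strand == "+":
                    seq[pos - 1] = "C"   # UGUAR needs G here
                else:
                    seq[pos + 1] = "G"   # revcomp context needs C here
                motif_planted = False
            site_rows.append((pos, strand, seq[pos], gene_id, motif_planted))
            idx += 1

    # decoy positions: intergenic block beyond the genes
    decoy_rows = []
    for k in range(10):                               # non-U reference
        pos = 15000 + 30 * k
        seq[pos] = "G"
        decoy_rows.append((pos, "+", "G", "non_u"))
    for k in range(5):                                # depth starvation
        pos = 15500 + 30 * k
        seq[pos] = "T"
        decoy_rows.append((pos, "+", "T", "low_depth"))
    for k in range(5):                                # dirty input background
        pos = 15800 + 30 * k
        seq[pos] = "T"
        decoy_rows.append((pos, "+", "T", "high_input"))

    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{_FIXTURE_CHROM}\n")
        s = "".join(seq)
        for i in range(0, len(s), 70):
            fh.write(s[i : i + 70] + "\n")
    paths["fasta"] = fasta

    gtf = out / "genes.gtf"
    with open(gtf, "w") as fh:
        for gene_id, biotype, strand, gstart, gend in _FIXTURE_GENES:
            attrs = f'gene_id "{gene_id}"; gene_biotype "{biotype}";'
            fh.write(
                f"{_FIXTURE_CHROM}\ttoy\tgene\t{gstart + 1}\t{gend + 1}\t.\t{strand}\t.\t{attrs}\n"
            )
    paths["gtf"] = gtf

    # --- pileups for two conditions ------------------------------------
    n_true = len(site_rows)
    f_ctrl = rng.uniform(0.3, 0.9, n_true)
    reduced = np.zeros(n_true, dtype=bool)
    reduced[rng.choice(n_true, size=15, replace=False)] = True
    f_kd = np.where(reduced, f_ctrl * 0.6, f_ctrl)

    def condition_counts(fractions: np.ndarray, cond_seed: int, prefix: str) -> pd.DataFrame:
        crng = np.random.default_rng(cond_seed)
        rows = []
        site_specs = [
            (pos, strand, ref, f, 100.0, 0.001)
            for (pos, strand, ref, _, _), f in zip(site_rows, fractions)
        ]
        for pos, strand, ref, cls in decoy_rows:
            depth_mean = 10.0 if cls == "low_depth" else 100.0
            e_i = 0.05 if cls == "high_input" else 0.001
            site_specs.append((pos, strand, ref, 0.5, depth_mean, e_i))
        for j in range(3):
            lib = f"{prefix}_bs_{j + 1}"
            for pos, strand, ref, f, dm, e_i in site_specs:
                depth = int(crng.poisson(dm))
                p = f * 0.95 + (1 - f) * 0.002
                dels = int(crng.binomial(depth, p)) if depth else 0
                rows.append((_FIXTURE_CHROM, pos, ref, depth, dels, lib))
        for j in range(3):
            lib = f"{prefix}_in_{j + 1}"
            for pos, strand, ref, f, dm, e_i in site_specs:
                depth = int(crng.poisson(dm))
                dels = int(crng.binomial(depth, e_i)) if depth else 0
                rows.append((_FIXTURE_CHROM, pos, ref, depth, dels, lib))
        return pd.DataFrame(
            rows, columns=["chrom", "pos0", "ref_base", "depth", "del_count", "library_id"]
        )

    sub = rng.integers(0, 2**31 - 1, size=4)
    for cond, fractions, cond_seed in (("ctrl", f_ctrl, int(sub[0])), ("kd", f_kd, int(sub[1]))):
        counts = condition_counts(fractions, cond_seed, cond)
        for lib, group in counts.groupby("library_id", sort=True):
            p = out / f"pileup_{lib}.tsv"
            write_pileup_tsv(group, p)
            paths[f"pileup_{lib}"] = p

    truth_psi = pd.DataFrame(
        {
            "chrom": _FIXTURE_CHROM,
            "pos": [r[0] + 1 for r in site_rows] + [r[0] + 1 for r in decoy_rows],
            "strand": [r[1] for r in site_rows] + [r[1] for r in decoy_rows],
            "ref_base": [r[2] for r in site_rows] + [r[2] for r in decoy_rows],
            "gene_id": [r[3] for r in site_rows] + [""] * len(decoy_rows),
            "motif_planted": [r[4] for r in site_rows] + [False] * len(decoy_rows),
            "true_fraction_ctrl": list(np.round(f_ctrl, 6)) + [0.0] * len(decoy_rows),
            "true_fraction_kd": list(np.round(f_kd, 6)) + [0.0] * len(decoy_rows),
            "decoy_class": [""] * n_true + [r[3] for r in decoy_rows],
        }
    )
    p = out / "truth_psi.tsv"
    truth_psi.to_csv(p, sep="\t", index=False)
    paths["truth_psi"] = p

    # --- KAS-style coverage --------------------------------------------
    cov_spec = CoverageSimSpec(
        n_genes=200, lambda_promoter=100.0, true_prr=1.0, prr_log_sigma=0.3,
        condition_effect=2.0, fraction_affected=0.5, seed=int(sub[2]),
    )
    tracks, cov_models, cov_truth = simulate_coverage(cov_spec)
    for cond in ("A", "B"):
        p = out / f"kas_{cond}.bedGraph"
        tracks[cond].to_bedgraph(p)
        paths[f"kas_{cond}"] = p
    p = out / "genes_prr.tsv"
    pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in cov_models],
            "chrom": [m.chrom for m in cov_models],
            "strand": [m.strand for m in cov_models],
            "tss": [m.tss for m in cov_models],
            "tes": [m.tes for m in cov_models],
            "biotype": [m.biotype for m in cov_models],
        }
    ).to_csv(p, sep="\t", index=False)
    paths["genes_prr"] = p
    p = out / "truth_prr.tsv"
    cov_truth.to_csv(p, sep="\t", index=False)
    paths["truth_prr"] = p

    # --- BIHIND Ct table ------------------------------------------------
    ct_seed = int(sub[3])
    quartets = simulate_ct(CtSimSpec(true_fraction=0.72, ct_noise_sd=0.1,
                                     n_replicates=3, seed=ct_seed, sample_label="siCtrl"))
    quartets += simulate_ct(CtSimSpec(true_fraction=0.48, ct_noise_sd=0.1,
                                      n_replicates=3, seed=ct_seed + 1, sample_label="siPUS7"))
    p = out / "ct_table.tsv"
    write_ct_tsv(quartets, p)
    paths["ct_table"] = p
    p = out / "truth_ct.tsv"
    pd.DataFrame(
        {"sample_label": ["siCtrl", "siPUS7"], "true_fraction": [0.72, 0.48]}
    ).to_csv(p, sep="\t", index=False)
    paths["truth_ct"] = p

    return paths
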