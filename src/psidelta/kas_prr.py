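"""Per-gene Pol II release ratio (PRR) from KAS-seq-style coverage.

Promoter-proximal pausing is read out as the ratio of transcription-
engaged Pol II signal on the early gene body versus the promoter:

    PRR = coverage(TSS+300 .. TSS+2000) / coverage(TSS-100 .. TSS+300)

Windows are strand-oriented; widths are 400 bp (promoter) and 1700 bp
(body). Genes with promoter coverage below 20 are discarded. Coverage is
the plain sum of per-base track values over the window, with no length
normalisation (the unequal widths are deliberate: the statistic compares
conditions gene-by-gene, where the geometry cancels). A per-base variant
is available for users who want width-comparable numbers.

Condition shifts in log2 PRR are assessed with a two-sided Wilcoxon
rank-sum (Mann-Whitney U) test on the kept-in-both gene set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import CoverageTrack, GeneModel, GenomicInterval

logger = logging.getLogger("psidelta")

PROMOTER_UPSTREAM = 100    # bp upstream of the TSS
PROMOTER_DOWNSTREAM = 300  # bp downstream of the TSS
BODY_END = 2000            # gene body runs TSS+300 .. TSS+2000
MIN_PROMOTER_COV = 20.0


@dataclass(frozen=True)
class WindowPair:
    gene_id: str
    promoter: GenomicInterval
    body: GenomicInterval
    strand: str


@dataclass(frozen=True)
class PRRRecord:
    gene_id: str
    promoter_cov: float
    body_cov: float
    prr: float | None
    log2_prr: float | None
    kept: bool


@dataclass(frozen=True)
class PRRComparison:
    deltas: dict[str, float]          # gene -> log2PRR_B - log2PRR_A
    wilcoxon_statistic: float
    p_value: float
    n_genes: int
    n_excluded_infinite: int
    ranked_genes: tuple[str, ...]     # descending by delta


def build_windows(models: Sequence[GeneModel]) -> list[WindowPair]:
    """Strand-aware promoter/body windows anchored at each gene's TSS.

    With 0-based TSS coordinate t:
      plus strand:  promoter [t-100, t+300), body [t+300, t+2000)
      minus strand: promoter [t-299, t+101), body [t-1999, t-299)
    (the minus-strand windows are the mirror image, covering the same
    transcript-relative offsets). Windows are truncated at position 0;
    genes whose body would be empty after truncation are dropped.
    """
    pairs: list[WindowPair] = []
    dropped = 0
    for m in models:
        t = m.tss
        if m.strand == "+":
            p_start, p_end = t - PROMOTER_UPSTREAM, t + PROMOTER_DOWNSTREAM
            b_start, b_end = t + PROMOTER_DOWNSTREAM, t + BODY_END
        else:
            p_start, p_end = t - PROMOTER_DOWNSTREAM + 1, t + PROMOTER_UPSTREAM + 1
            b_start, b_end = t - BODY_END + 1, t - PROMOTER_DOWNSTREAM + 1
        p_start, b_start = max(p_start, 0), max(b_start, 0)
        if b_end <= b_start:
            dropped += 1
            continue
        p_end = max(p_end, p_start + 1)
        pairs.append(
            WindowPair(
                m.gene_id,
                GenomicInterval(m.chrom, p_start, p_end, m.strand),
                GenomicInterval(m.chrom, b_start, b_end, m.strand),
                m.strand,
            )
        )
    if dropped:
        logger.warning("build_windows: %d genes dropped (empty body after clamp)", dropped)
    return pairs


def window_coverage(track: CoverageTrack, window: GenomicInterval) -> float:
    """Sum of per-base track values over the window; uncovered bases are 0."""
    return track.coverage(window)


def compute_prr(
    promoter_cov: float,
    body_cov: float,
    min_promoter: float = MIN_PROMOTER_COV,
    gene_id: str = "",
    per_bp: bool = False,
) -> PRRRecord:
    """PRR = body coverage / promoter coverage, with the low-promoter filter.

    Genes with promoter coverage below ``min_promoter`` are discarded
    (kept=False); coverage exactly at the threshold is kept. ``per_bp``
    rescales both coverages to per-base means before the ratio.
    body_cov = 0 yields prr = 0 with log2 = -inf, which downstream rank
    tests exclude.
    """
    if promoter_cov < 0 or body_cov < 0:
        raise ValueError("coverage must be non-negative")
    if promoter_cov < min_promoter:
        return PRRRecord(gene_id, promoter_cov, body_cov, None, None, False)
    p, b = promoter_cov, body_cov
    if per_bp:
        p /= PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM
        b /= BODY_END - PROMOTER_DOWNSTREAM
    prr = b / p
    log2 = math.log2(prr) if prr > 0 else -math.inf
    return PRRRecord(gene_id, promoter_cov, body_cov, prr, log2, True)


def prr_table(
    track: CoverageTrack,
    models: Sequence[GeneModel],
    min_promoter: float = MIN_PROMOTER_COV,
    per_bp: bool = False,
) -> list[PRRRecord]:
    """Windows + coverage + PRR for every gene, one condition."""
    return [
        compute_prr(
            window_coverage(track, w.promoter),
            window_coverage(track, w.body),
            min_promoter,
            gene_id=w.gene_id,
            per_bp=per_bp,
        )
        for w in build_windows(models)
    ]


def compare_conditions(
    a: Sequence[PRRRecord],
    b: Sequence[PRRRecord],
    paired: bool = False,
) -> PRRComparison:
    """Compare log2 PRR distributions between two conditions.

    Only genes kept in both conditions enter; -inf log2 values (zero body
    coverage) are excluded and counted. Default is the unpaired two-sided
    rank-sum test on the two distributions; ``paired`` switches to the
    Wilcoxon signed-rank test on per-gene deltas.
    """
    kept_a = {r.gene_id: r for r in a if r.kept}
    kept_b = {r.gene_id: r for r in b if r.kept}
    shared = sorted(set(kept_a) & set(kept_b))
    finite = [
        g for g in shared
        if math.isfinite(kept_a[g].log2_prr) and math.isfinite(kept_b[g].log2_prr)
    ]
    n_excluded = len(shared) - len(finite)
    if len(finite) < 2:
        raise ValueError(f"need >= 2 shared finite genes, have {len(finite)}")
    xa = np.array([kept_a[g].log2_prr for g in finite])
    xb = np.array([kept_b[g].log2_prr for g in finite])
    if paired:
        if np.allclose(xa, xb):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(xb, xa, alternative="two-sided")
    else:
        stat, p = stats.mannwhitneyu(xb, xa, alternative="two-sided")
    deltas = {g: float(kept_b[g].log2_prr - kept_a[g].log2_prr) for g in finite}
    ranked = tuple(sorted(deltas, key=lambda g: (-deltas[g], g)))
    return PRRComparison(
        deltas=deltas,
        wilcoxon_statistic=float(stat),
        p_value=float(p),
        n_genes=len(finite),
        n_excluded_infinite=n_excluded,
        ranked_genes=ranked,
    )


def metagene_profile(
    track: CoverageTrack,
    models: Sequence[GeneModel],
    upstream_bp: int = 2000,
    downstream_bp: int = 2000,
    body_bins: int = 100,
    flank_bin_bp: int = 100,
    normalize: str = "raw",
) -> tuple[np.ndarray, np.ndarray]:
    """Strand-oriented per-gene coverage profiles around gene bodies.

    Each row is one gene: fixed-width upstream bins, ``body_bins`` bins
    scaled over the gene body, fixed-width downstream bins, all 5'->3'.
    Bin values are mean per-base coverage; ``normalize='rpkm'`` rescales
    by 1e9 / total track mass (reads-per-kilobase-per-million analogue for
    per-base tracks). Genes shorter than ``body_bins`` bases are skipped.

    Returns (matrix, mean_curve).
    """
    if normalize not in ("raw", "rpkm"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    up_bins = upstream_bp // flank_bin_bp
    down_bins = downstream_bp // flank_bin_bp
    rows = []
    skipped = 0
    for m in models:
        span = abs(m.tes - m.tss) + 1
        if span < body_bins:
            skipped += 1
            continue
        left = min(m.tss, m.tes)
        start = left - (upstream_bp if m.strand == "+" else downstream_bp)
        end = left + span + (downstream_bp if m.strand == "+" else upstream_bp)
        vals = np.zeros(end - start)
        lo = max(start, 0)
        if end > lo:
            vals[lo - start:] = track.per_base(GenomicInterval(m.chrom, lo, end))
        if m.strand == "-":
            vals = vals[::-1]
        up = vals[: up_bins * flank_bin_bp].reshape(up_bins, flank_bin_bp).mean(axis=1)
        body_vals = vals[upstream_bp : upstream_bp + span]
        edges = np.linspace(0, span, body_bins + 1).astype(int)
        body = np.array(
            [body_vals[edges[i] : edges[i + 1]].mean() for i in range(body_bins)]
        )
        down_vals = vals[upstream_bp + span : upstream_bp + span + down_bins * flank_bin_bp]
        down = down_vals.reshape(down_bins, flank_bin_bp).mean(axis=1)
        rows.append(np.concatenate([up, body, down]))
    if skipped:
        logger.warning("metagene_profile: %d short genes skipped", skipped)
    if not rows:
        n = up_bins + body_bins + down_bins
        return np.zeros((0, n)), np.zeros(n)
    matrix = np.vstack(rows)
    if normalize == "rpkm":
        total = track.total_mass()
        if total > 0:
            matrix = matrix * (1e9 / total)
    return matrix, matrix.mean(axis=0)


def prr_records_to_frame(records: Sequence[PRRRecord]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "promoter_cov": [r.promoter_cov for r in records],
            "body_cov": [r.body_cov for r in records],
            "prr": [r.prr for r in records],
            "log2_prr": [r.log2_prr for r in records],
            "kept": [r.kept for r in records],
        }
    )
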