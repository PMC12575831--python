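"""Pseudouridine (Ψ) site calling from bisulfite-induced deletion signatures.

Ψ sites leave a characteristic deletion at the modified uridine during
reverse transcription of bisulfite-treated RNA. A candidate site must
clear five filters, evaluated with strict inequalities:

1. deletion ratio above ``min_treated_ratio`` (default 0.05) with deletion
   count above ``min_del_count`` (default 4) in every BS-treated replicate;
2. deletion ratio below ``max_input_ratio`` (default 0.02) in every
   untreated input replicate;
3. read depth above ``min_depth`` (default 20) in every treated and input
   replicate;
4. the reference base is a U on the transcribed strand (T on the plus
   strand of the DNA reference, A on the minus strand);
5. the signature is present in every biological replicate (a replicate
   missing from the table counts as failing).

The Ψ fraction reported per replicate is the raw deletion ratio; a
calibration hook (ratio -> fraction) can be injected for chemistries whose
deletion rate is not 1:1 with stoichiometry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneModel, SequenceStore

logger = logging.getLogger("psidelta")

CRITERIA = (
    "treated_signal",   # ratio > min_treated_ratio and del_count > min_del_count
    "input_background",  # ratio < max_input_ratio in every input replicate
    "depth",             # depth > min_depth in every library
    "u_site",            # reference base is U on the transcribed strand
    "all_replicates",    # observed in every treated replicate
)

DEFAULT_SPECIES_PRIORITY = ("tRNA", "snRNA", "lncRNA", "intron", "mRNA", "other")


@dataclass(frozen=True)
class SiteCounts:
    chrom: str
    pos0: int
    ref_base: str
    depth: int
    del_count: int
    library_id: str

    def __post_init__(self) -> None:
        if self.del_count > self.depth:
            raise ValueError("del_count exceeds depth")
        if self.depth < 0 or self.del_count < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class LibrarySet:
    condition: str
    treated_replicates: tuple[str, ...]
    input_replicates: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.treated_replicates or not self.input_replicates:
            raise ValueError("need at least one treated and one input replicate")
        ids = list(self.treated_replicates) + list(self.input_replicates)
        if len(set(ids)) != len(ids):
            raise ValueError("library ids must be unique")


@dataclass(frozen=True)
class CallParams:
    """Thresholds of the five-criterion filter; all strict inequalities."""

    min_treated_ratio: float = 0.05
    min_del_count: int = 4
    max_input_ratio: float = 0.02
    min_depth: int = 20
    require_all_replicates: bool = True
    require_u_site: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.max_input_ratio < self.min_treated_ratio <= 1):
            raise ValueError("require 0 <= max_input_ratio < min_treated_ratio <= 1")


@dataclass
class PsiSite:
    chrom: str
    pos0: int
    strand: str
    ref_base: str
    per_replicate_fraction: list[float]
    mean_fraction: float
    per_replicate_input_ratio: list[float]
    motif_hit: bool = False
    species: str = "other"
    pass_flags: dict[str, bool] = field(default_factory=dict)
    strand_assumed: bool = False

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos0 + 1}:{self.strand}"


@dataclass
class DifferentialResult:
    site: str
    mean_fraction_a: float
    mean_fraction_b: float
    delta: float
    t_statistic: float
    p_value: float
    direction: str
    significant: bool
    degenerate: bool = False
    fdr: float | None = None


def deletion_ratio(depth: int, del_count: int) -> float:
    """Deletions over depth at one site; the raw Ψ-stoichiometry estimate."""
    if depth <= 0:
        raise ZeroDivisionError("deletion ratio undefined at zero depth")
    if del_count > depth:
        raise ValueError("del_count exceeds depth")
    return del_count / depth


def _u_base_for_strand(strand: str) -> str:
    return "T" if strand == "+" else "A"


def site_strand(
    chrom: str,
    pos0: int,
    models: Sequence[GeneModel] | None,
) -> tuple[str, bool]:
    """Transcribed strand at a position from overlapping gene models.

    Returns (strand, assumed): intergenic sites default to '+' with the
    assumption flagged. When models on both strands overlap, '+' wins
    deterministically and the ambiguity is flagged.
    """
    if models:
        strands = {
            m.strand
            for m in models
            if m.chrom == chrom and m.span.start <= pos0 < m.span.end
        }
        if len(strands) == 1:
            return strands.pop(), False
        if len(strands) == 2:
            return "+", True
    return "+", True


def call_sites(
    counts: pd.DataFrame,
    libs: LibrarySet,
    params: CallParams = CallParams(),
    seqs: SequenceStore | None = None,
    gene_models: Sequence[GeneModel] | None = None,
    calibration: Callable[[float], float] | None = None,
    collect_stats: dict | None = None,
) -> list[PsiSite]:
    """Apply the five-criterion cascade to a SiteCounts table.

    ``counts`` is the frame produced by :func:`psidelta.core_io.read_pileup_counts`
    (columns chrom, pos0, ref_base, depth, del_count, library_id), pooled
    over all libraries of one condition. A site absent from an input
    library's table fails the depth criterion — absence of evidence is not
    evidence of low background. Output is sorted by (chrom, pos0).

    ``collect_stats``, if given, receives per-criterion failure counts.
    """
    calibrate = calibration or (lambda r: r)
    treated = list(libs.treated_replicates)
    inputs = list(libs.input_replicates)

    wide_depth = counts.pivot_table(
        index=["chrom", "pos0", "ref_base"], columns="library_id",
        values="depth", aggfunc="first",
    )
    wide_del = counts.pivot_table(
        index=["chrom", "pos0", "ref_base"], columns="library_id",
        values="del_count", aggfunc="first",
    )
    for lib in treated + inputs:
        if lib not in wide_depth.columns:
            wide_depth[lib] = np.nan
            wide_del[lib] = np.nan

    t_depth = wide_depth[treated].to_numpy(float)
    t_del = wide_del[treated].to_numpy(float)
    i_depth = wide_depth[inputs].to_numpy(float)
    i_del = wide_del[inputs].to_numpy(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        t_ratio = np.where(t_depth > 0, t_del / t_depth, np.nan)
        i_ratio = np.where(i_depth > 0, i_del / i_depth, np.nan)

    present_t = ~np.isnan(t_depth)
    present_i = ~np.isnan(i_depth)

    # criterion 5: deletion signature observed in every treated replicate
    c5 = present_t.all(axis=1) if params.require_all_replicates else present_t.any(axis=1)
    # criterion 1: signal in every treated replicate, strict thresholds
    with np.errstate(invalid="ignore"):
        sig = (t_ratio > params.min_treated_ratio) & (t_del > params.min_del_count)
    c1 = np.where(present_t, sig, False).all(axis=1)
    # criterion 2: background below threshold in every input replicate;
    # a missing input library fails depth (c3), not this one
    c2 = np.where(present_i, i_ratio < params.max_input_ratio, True).all(axis=1)
    # criterion 3: depth above threshold in every treated and input library
    c3 = (
        np.where(present_t, t_depth > params.min_depth, False).all(axis=1)
        & np.where(present_i, i_depth > params.min_depth, False).all(axis=1)
    )

    index = wide_depth.index.to_frame(index=False)
    chroms = index["chrom"].to_numpy()
    positions = index["pos0"].to_numpy()
    refs = index["ref_base"].astype(str).str.upper().to_numpy()

    # criterion 4: U on the transcribed strand
    strands = np.empty(len(index), dtype=object)
    assumed = np.zeros(len(index), dtype=bool)
    for i in range(len(index)):
        strands[i], assumed[i] = site_strand(chroms[i], int(positions[i]), gene_models)
    if params.require_u_site:
        expected = np.where(strands == "-", "A", "T")
        c4 = refs == expected
        if seqs is not None:
            ref_ok = np.array(
                [seqs.base_at(c, int(p)) == r for c, p, r in zip(chroms, positions, refs)]
            )
            c4 &= ref_ok
    else:
        c4 = np.ones(len(index), dtype=bool)

    passed = c1 & c2 & c3 & c4 & c5
    if collect_stats is not None:
        collect_stats.update({
            "candidates": int(len(index)),
            "fail_treated_signal": int((~c1).sum()),
            "fail_input_background": int((~c2).sum()),
            "fail_depth": int((~c3).sum()),
            "fail_u_site": int((~c4).sum()),
            "fail_all_replicates": int((~c5).sum()),
            "called": int(passed.sum()),
        })

    sites: list[PsiSite] = []
    for i in np.flatnonzero(passed):
        fractions = [calibrate(r) for r in t_ratio[i]]
        in_ratios = [r for r, ok in zip(i_ratio[i], present_i[i]) if ok]
        sites.append(
            PsiSite(
                chrom=str(chroms[i]),
                pos0=int(positions[i]),
                strand=str(strands[i]),
                ref_base=str(refs[i]),
                per_replicate_fraction=[float(f) for f in fractions],
                mean_fraction=float(np.mean(fractions)),
                per_replicate_input_ratio=[float(r) for r in in_ratios],
                pass_flags={name: True for name in CRITERIA},
                strand_assumed=bool(assumed[i]),
            )
        )
    sites.sort(key=lambda s: (s.chrom, s.pos0))
    return sites


# ---------------------------------------------------------------------------
# Differential pseudouridylation
# ---------------------------------------------------------------------------

def pooled_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, bool]:
    """Two-sided two-sample Student's t with pooled variance.

    Degenerate zero-variance cases get the conventions p=1 (equal means)
    and p=0 (unequal means), flagged via the returned boolean.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return math.inf if b.mean() < a.mean() else -math.inf, 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), False


def differential_sites(
    fractions_a: Mapping[str, Sequence[float]],
    fractions_b: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    welch: bool = False,
) -> list[DifferentialResult]:
    """Per-site two-tailed Student's t test between two conditions.

    Mirrors the published rule: significance is raw p < alpha with no
    multiple-testing correction; a BH-FDR column is attached for reference
    but never gates the call. Sites lacking >= 2 replicates in either
    condition are excluded with a warning. Sorted by ascending p.
    """
    results: list[DifferentialResult] = []
    skipped = 0
    for key in sorted(set(fractions_a) & set(fractions_b)):
        a = np.asarray(fractions_a[key], float)
        b = np.asarray(fractions_b[key], float)
        if len(a) < 2 or len(b) < 2:
            skipped += 1
            continue
        if welch:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            t, p, degenerate = float(t), float(p), False
            if math.isnan(p):  # zero variance both groups
                t, p, degenerate = pooled_t_test(a, b)
        else:
            t, p, degenerate = pooled_t_test(a, b)
        delta = float(b.mean() - a.mean())
        results.append(
            DifferentialResult(
                site=key,
                mean_fraction_a=float(a.mean()),
                mean_fraction_b=float(b.mean()),
                delta=delta,
                t_statistic=t,
                p_value=p,
                direction="reduced" if delta < 0 else "increased",
                significant=bool(p < alpha),
                degenerate=degenerate,
            )
        )
    if skipped:
        logger.warning("differential_sites: %d sites skipped (<2 replicates)", skipped)
    if results:
        pvals = np.array([r.p_value for r in results])
        m = len(pvals)
        order = np.argsort(pvals)
        fdr = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            running = min(running, pvals[idx] * m / rank)
            fdr[idx] = running
        for r, q in zip(results, fdr):
            r.fdr = float(q)
    results.sort(key=lambda r: (r.p_value, r.site))
    return results


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate_motif(
    seqs: SequenceStore,
    chrom: str,
    pos0: int,
    strand: str,
    motif: str = "UGUAR",
    psi_offset: int = 2,
) -> bool:
    """Test the transcribed-strand sequence context against a consensus.

    The PUS7 consensus is UGUAR (R = A or G) with the substrate uridine at
    the central position (offset 2 of the 5-mer). Minus-strand sites are
    evaluated on the reverse complement. N never matches; sites too close
    to a contig edge return False with a warning.
    """
    dna_motif = motif.upper().replace("U", "T")
    k = len(dna_motif)
    if strand == "+":
        start = pos0 - psi_offset
        context = seqs.fetch(chrom, start, start + k)
    else:
        end = pos0 + psi_offset + 1
        context = SequenceStore.revcomp(seqs.fetch(chrom, end - k, end))
    if "N" in context:
        logger.warning("motif context at %s:%d touches contig edge or N", chrom, pos0)
        return False
    iupac = {"R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC"}
    for obs, want in zip(context, dna_motif):
        allowed = iupac.get(want, want)
        if obs not in allowed:
            return False
    return True


def assign_species(
    chrom: str,
    pos0: int,
    models: Sequence[GeneModel],
    exons: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    priority: Sequence[str] = DEFAULT_SPECIES_PRIORITY,
) -> str:
    """Label a site by the highest-priority overlapping RNA species.

    Protein-coding overlap resolves to "mRNA" inside an annotated exon and
    "intron" otherwise (a missing exon list means the whole gene counts as
    exonic). Sites overlapping nothing are "other".
    """
    labels = set()
    for m in models:
        if m.chrom != chrom or not (m.span.start <= pos0 < m.span.end):
            continue
        if m.biotype == "protein_coding":
            gene_exons = (exons or {}).get(m.gene_id)
            if gene_exons is None:
                labels.add("mRNA")
            elif any(s <= pos0 < e for s, e in gene_exons):
                labels.add("mRNA")
            else:
                labels.add("intron")
        else:
            labels.add(m.biotype)
    for label in priority:
        if label in labels:
            return label
    return next(iter(sorted(labels)), "other")


def annotate_sites(
    sites: Iterable[PsiSite],
    seqs: SequenceStore | None = None,
    models: Sequence[GeneModel] | None = None,
    exons: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    motif: str = "UGUAR",
) -> list[PsiSite]:
    """Attach motif and RNA-species annotation to called sites, in place."""
    sites = list(sites)
    for s in sites:
        if seqs is not None:
            s.motif_hit = annotate_motif(seqs, s.chrom, s.pos0, s.strand, motif)
        if models is not None:
            s.species = assign_species(s.chrom, s.pos0, models, exons)
    return sites


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def sites_to_frame(sites: Sequence[PsiSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos0 + 1 for s in sites],
            "strand": [s.strand for s in sites],
            "ref_base": [s.ref_base for s in sites],
            "replicate_fractions": [
                ",".join(f"{f:.6g}" for f in s.per_replicate_fraction) for s in sites
            ],
            "mean_fraction": [s.mean_fraction for s in sites],
            "input_ratios": [
                ",".join(f"{r:.6g}" for r in s.per_replicate_input_ratio) for s in sites
            ],
            "motif_hit": [s.motif_hit for s in sites],
            "species": [s.species for s in sites],
            "strand_assumed": [s.strand_assumed for s in sites],
        }
    )


def differential_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [r.site for r in results],
            "mean_fraction_a": [r.mean_fraction_a for r in results],
            "mean_fraction_b": [r.mean_fraction_b for r in results],
            "delta": [r.delta for r in results],
            "t_statistic": [r.t_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "direction": [r.direction for r in results],
            "significant": [r.significant for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
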