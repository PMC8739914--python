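"""Synthetic pipeline inputs with known ground truth.

Every generator is a pure function of its parameters and an integer seed,
so outputs are byte-reproducible. The generators emulate the statistical
structure the downstream analysis assumes:

* a genome carrying designed pre-miRNA hairpins (stem >= 18 pairs, 2-nt 3'
  overhang duplex geometry, ~80% of precursors < 150 nt) and siRNA loci;
* sRNA libraries with the 21/24-nt bimodal length profile — miRNA loci
  emit reads stacked on mature/star 5' ends at a controlled precision,
  siRNA loci emit dispersed 24-mers;
* degradome 5'-end densities peaking at the planted cleavage site
  (opposite miRNA positions 10–11);
* tissue x replicate expression with an exact planted fraction of strictly
  anti-correlated miRNA–target pairs;
* promoters with exact-consensus TF binding sites for JASPAR-style PWMs.

Expression profiles are lognormal with sigma_log = 1.5 by default: heavy
tissue-structure matching the orders-of-magnitude RPM range real miRNA
panels show, which also keeps chance anti-correlation between unrelated
profiles rare.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fold import default_engine, pair_table
from .types import ExpressionMatrix, GenomicInterval, Pwm, ReadStack, revcomp

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ------------------------------------------------------------------- truth


@dataclass
class PlantedMirna:
    locus_id: str
    precursor: GenomicInterval
    mature: GenomicInterval
    star: GenomicInterval
    family: str
    precursor_seq: str  # precursor sense strand
    mature_seq: str
    star_seq: str
    arm: str  # which arm carries the mature: "5p" | "3p"
    mature_local: tuple[int, int]  # offsets on the sense precursor
    star_local: tuple[int, int]


@dataclass
class PlantedTarget:
    mirna_id: str
    transcript_id: str
    site_start: int      # 0-based on transcript
    cleavage_pos: int    # 1-based, opposite miRNA position 10


@dataclass
class TruthSet:
    """Ground truth for one synthetic study; filled in incrementally."""

    rng_seed: int
    genome_lengths: dict[str, int] = field(default_factory=dict)
    planted_mirna_loci: list[PlantedMirna] = field(default_factory=list)
    planted_sirna_loci: list[GenomicInterval] = field(default_factory=list)
    planted_target_pairs: list[PlantedTarget] = field(default_factory=list)
    planted_negative_fraction: float = 0.0
    planted_negative_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_tfbs: list[tuple[str, str, int]] = field(default_factory=list)
    planted_conservation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.planted_negative_fraction <= 1.0):
            raise ValueError("planted_negative_fraction outside [0,1]")

    def validate(self) -> None:
        for pm in self.planted_mirna_loci:
            L = self.genome_lengths[pm.precursor.chrom]
            if pm.precursor.end > L:
                raise ValueError(f"{pm.locus_id} exceeds genome bounds")
            if not (pm.precursor.contains(pm.mature) and pm.precursor.contains(pm.star)):
                raise ValueError(f"{pm.locus_id} arms outside precursor")
            if pm.mature.overlaps(pm.star):
                raise ValueError(f"{pm.locus_id} arms overlap")
            if pm.mature.strand != pm.star.strand:
                raise ValueError(f"{pm.locus_id} arms on different strands")


# ------------------------------------------------------- hairpin construction


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _design_hairpin(rng: np.random.Generator, n_stem_mismatches: int = 2
                    ) -> tuple[str, tuple[int, int], tuple[int, int], str]:
    """Design one pre-miRNA: ext5 + arm5 + loop + arm3 + ext3.

    The mature/star duplex occupies the arm regions with the canonical
    2-nt 3' overhang geometry: arm5[i] pairs arm3[m-3-i] for i <= m-3.
    Planted lower-stem mismatches go into the ext regions only, so the
    mature-arm always pairs >= m-2 >= 18 bases to the star arm.

    Returns (precursor sense sequence, mature local span, star local span,
    arm label).
    """
    m = int(rng.choice([20, 21, 22, 23, 24], p=[0.10, 0.60, 0.15, 0.10, 0.05]))
    # target precursor length: 80% below 150 nt
    if rng.random() < 0.80:
        total = int(rng.integers(90, 150))
    else:
        total = int(rng.integers(150, 221))
    loop = int(rng.integers(8, 41))
    loop = min(loop, total - 2 * m - 16)  # keep ext >= 8 per side
    loop = max(loop, 8)
    ext = (total - 2 * m - loop) // 2
    ext = max(ext, 8)

    arm = "5p" if rng.random() < 0.5 else "3p"
    # mature sequence with the plant-typical 5' U bias
    first = "T" if rng.random() < 0.6 else str(rng.choice(_BASES))
    mat = first + _rand_seq(rng, m - 1)

    ext5 = _rand_seq(rng, ext)
    if arm == "5p":
        arm5 = mat
        partner = "".join(_COMP[b] for b in arm5[: m - 2])[::-1]
        # the star 3' overhang must pair neither the facing lower stem nor
        # the mature 5' end (a pairable tail lets the duplex register slide)
        tail = _nonpairing_seq(rng, 2, mat[0] + mat[1])
        ext5 = ext5[:-4] + _nonpairing_seq(rng, 4, tail)
        arm3 = partner + tail
    else:
        arm3 = mat
        # the mature's unpaired 3' tail must not pair into the lower stem
        ext5 = ext5[:-4] + _nonpairing_seq(rng, 4, mat[-2] + mat[-1])
        partner = "".join(_COMP[b] for b in arm3[: m - 2])[::-1]
        arm5 = partner + _nonpairing_seq(rng, 2, mat[0] + mat[1])
    ext3 = revcomp(ext5)
    # planted lower-stem mismatches (<= 4 per design)
    for pos in rng.choice(ext, size=min(n_stem_mismatches, 4), replace=False):
        alt = [b for b in "ACGT" if b != ext3[pos] and b != _COMP[ext5[ext - 1 - pos]]]
        ext3 = ext3[:pos] + str(rng.choice(alt)) + ext3[pos + 1:]

    pre = ext5 + arm5 + _loop_seq(rng, loop, arm5) + arm3 + ext3
    a5 = (ext, ext + len(arm5))
    a3 = (ext + len(arm5) + loop, ext + len(arm5) + loop + len(arm3))
    if arm == "5p":
        mature_local, star_local = a5, a3
    else:
        mature_local, star_local = a3, a5
    return pre, mature_local, star_local, arm


def _partners(base: str, wobble: bool = True) -> set[str]:
    out = {_COMP[base]}
    if wobble and base in "GT":
        out.add({"G": "T", "T": "G"}[base])
    return out


def _nonpairing_seq(rng: np.random.Generator, n: int, avoid: str) -> str:
    """``n`` bases, none able to pair with any base in ``avoid`` (wobble
    included where the alphabet allows, Watson-Crick always)."""
    banned = set().union(*(_partners(b) for b in avoid))
    allowed = [b for b in "ACGT" if b not in banned]
    if not allowed:
        banned = set().union(*(_partners(b, wobble=False) for b in avoid))
        allowed = [b for b in "ACGT" if b not in banned]
    return "".join(rng.choice(np.array(allowed), size=n))


def _loop_seq(rng: np.random.Generator, n: int, arm5: str) -> str:
    """A/C-only loop (cannot self-pair). The two loop bases adjacent to the
    5' arm are constrained so a folding engine cannot extend the stem by
    pairing them with the arm's unpaired 2-nt tail."""
    seq = list(rng.choice(np.array(list("AC")), size=n))

    def allowed(partner: str) -> str:
        ok = [b for b in "AC" if b != _COMP.get(partner)]
        return str(rng.choice(ok)) if ok else "C"

    if n >= 1:
        seq[-1] = allowed(arm5[-2])
    if n >= 2:
        seq[-2] = allowed(arm5[-1])
    return "".join(seq)


def _design_recoverable(pre: str, ml: tuple[int, int], sl: tuple[int, int],
                        engine) -> bool:
    """Postcondition check for one designed hairpin: under the folding
    engine's structure, the partners of the mature (minus its 2-nt 3'
    overhang) span exactly the star minus its own overhang — i.e. the
    minimum-energy register reproduces the planted duplex geometry."""
    structure, _ = engine.fold(pre)
    try:
        pt = pair_table(structure)
    except ValueError:
        return False
    partners = [pt[i] for i in range(ml[0], ml[1] - 2) if pt[i] >= 0]
    if len(partners) < 18:
        return False
    lo, hi = min(partners), max(partners)
    if lo != sl[0] or hi != sl[1] - 3:
        return False
    # the mature overhang must not pair just outside the star span, which
    # would widen the derived star by the junction-adjacency rule
    for i in (ml[1] - 2, ml[1] - 1):
        j = pt[i]
        if j >= 0 and (lo - 2 <= j < lo or hi < j <= hi + 2):
            return False
    return True


def generate_genome_with_hairpins(
    n_mirna: int = 30,
    n_sirna: int = 30,
    genome_length: int = 1_000_000,
    seed: int = 0,
    chrom: str = "chr1",
    family_fraction: float = 0.75,
    min_gap: int = 200,
) -> tuple[dict[str, str], TruthSet]:
    """Random genome with planted miRNA hairpins and siRNA loci.

    ``family_fraction`` controls how many distinct families the miRNA loci
    fall into; members of one family share the mature sequence exactly.
    Raises ``ValueError`` when the requested loci cannot be packed without
    overlap.
    """
    rng = np.random.default_rng(seed)
    truth = TruthSet(rng_seed=seed)

    n_fam = max(1, int(round(n_mirna * family_fraction)))
    fam_of = list(range(n_fam)) + [int(rng.integers(0, n_fam))
                                   for _ in range(n_mirna - n_fam)]
    rng.shuffle(fam_of)

    # design hairpins; family members share the mature by re-design with a
    # pinned mature sequence. Each design is folded and rejection-sampled
    # until the minimum-energy register reproduces the planted duplex, so
    # the truth is structurally self-consistent by construction.
    engine = default_engine()
    designs: list[tuple[str, tuple[int, int], tuple[int, int], str]] = []
    fam_mature: dict[int, str] = {}
    for i in range(n_mirna):
        fam = fam_of[i]
        pinned = fam_mature.get(fam)
        for _attempt in range(200):
            if pinned is None:
                pre, ml, sl, arm = _design_hairpin(rng)
            else:
                pre, ml, sl, arm = _redesign_with_mature(rng, pinned)
            if _design_recoverable(pre, ml, sl, engine):
                break
        else:
            raise RuntimeError("could not design a recoverable hairpin")
        if pinned is None:
            fam_mature[fam] = pre[ml[0]:ml[1]]
        designs.append((pre, ml, sl, arm))

    sirna_lens = [int(rng.integers(300, 801)) for _ in range(n_sirna)]
    sizes = [len(d[0]) for d in designs] + sirna_lens
    kinds = ["mirna"] * n_mirna + ["sirna"] * n_sirna
    order = rng.permutation(len(sizes))

    spare = genome_length - sum(sizes) - (len(sizes) + 1) * min_gap
    if spare < 0:
        raise ValueError(
            f"cannot pack {n_mirna}+{n_sirna} loci ({sum(sizes)} nt + gaps) "
            f"into {genome_length} nt")
    gap_extra = rng.multinomial(spare, [1.0 / (len(sizes) + 1)] * (len(sizes) + 1))

    genome = list(_rand_seq(rng, genome_length))
    pos = 0
    mi = 0
    for slot, oi in enumerate(order):
        pos += min_gap + int(gap_extra[slot])
        size = sizes[oi]
        if kinds[oi] == "sirna":
            truth.planted_sirna_loci.append(
                GenomicInterval(chrom, pos, pos + size, "+"))
        else:
            pre, ml, sl, arm = designs[oi]
            strand = "+" if rng.random() < 0.5 else "-"
            genome[pos:pos + size] = list(pre if strand == "+" else revcomp(pre))
            T = len(pre)

            def to_genomic(span: tuple[int, int]) -> GenomicInterval:
                if strand == "+":
                    return GenomicInterval(chrom, pos + span[0], pos + span[1], "+")
                return GenomicInterval(chrom, pos + T - span[1], pos + T - span[0], "-")

            mi += 1
            pm = PlantedMirna(
                locus_id=f"planted-mir-{mi:03d}",
                precursor=GenomicInterval(chrom, pos, pos + T, strand),
                mature=to_genomic(ml), star=to_genomic(sl),
                family=f"FAM{fam_of[oi] + 1:03d}",
                precursor_seq=pre,
                mature_seq=pre[ml[0]:ml[1]], star_seq=pre[sl[0]:sl[1]],
                arm=arm, mature_local=ml, star_local=sl)
            truth.planted_mirna_loci.append(pm)
        pos += size
    truth.genome_lengths[chrom] = genome_length
    truth.validate()
    return {chrom: "".join(genome)}, truth


def _redesign_with_mature(rng: np.random.Generator, mature: str
                          ) -> tuple[str, tuple[int, int], tuple[int, int], str]:
    """Design a fresh hairpin around a pinned mature sequence."""
    m = len(mature)
    total = int(rng.integers(90, 150)) if rng.random() < 0.8 else int(rng.integers(150, 221))
    loop = max(8, min(int(rng.integers(8, 41)), total - 2 * m - 16))
    ext = max(8, (total - 2 * m - loop) // 2)
    arm = "5p" if rng.random() < 0.5 else "3p"
    ext5 = _rand_seq(rng, ext)
    if arm == "5p":
        arm5 = mature
        tail = _nonpairing_seq(rng, 2, mature[0] + mature[1])
        ext5 = ext5[:-4] + _nonpairing_seq(rng, 4, tail)
        arm3 = "".join(_COMP[b] for b in arm5[: m - 2])[::-1] + tail
    else:
        arm3 = mature
        ext5 = ext5[:-4] + _nonpairing_seq(rng, 4, mature[-2] + mature[-1])
        arm5 = ("".join(_COMP[b] for b in arm3[: m - 2])[::-1]
                + _nonpairing_seq(rng, 2, mature[0] + mature[1]))
    ext3 = revcomp(ext5)
    pre = ext5 + arm5 + _loop_seq(rng, loop, arm5) + arm3 + ext3
    a5 = (ext, ext + len(arm5))
    a3 = (ext + len(arm5) + loop, ext + len(arm5) + loop + len(arm3))
    return (pre, a5, a3, arm) if arm == "5p" else (pre, a3, a5, arm)


# ------------------------------------------------------------ sRNA libraries


def locus_weights(truth: TruthSet, tissue: str | None = None,
                  sigma_log: float = 1.5,
                  tissue_sigma: float = 0.8) -> dict[str, float]:
    """Per-locus relative abundance, a function of the truth seed (and the
    tissue label) only: replicate libraries generated with different seeds
    share locus means, while tissues differ by a lognormal effect."""
    rng = np.random.default_rng((truth.rng_seed * 2654435761 + 777) % 2**31)
    w = rng.lognormal(0.0, sigma_log, len(truth.planted_mirna_loci))
    if tissue is not None:
        tseed = int.from_bytes(hashlib.sha256(
            f"{truth.rng_seed}:{tissue}".encode()).digest()[:4], "big")
        trng = np.random.default_rng(tseed)
        w = w * trng.lognormal(0.0, tissue_sigma, len(w))
    return {pm.locus_id: float(x) for pm, x in zip(truth.planted_mirna_loci, w)}


def generate_srna_library(
    truth: TruthSet,
    genome: dict[str, str],
    depth: int,
    precision: float = 0.9,
    seed: int = 0,
    library_id: str = "lib",
    mirna_fraction: float = 0.60,
    sirna_fraction: float = 0.35,
    dispersion: float = 0.05,
    mature_share: float = 0.75,
    tissue: str | None = None,
) -> list[ReadStack]:
    """One sequencing library as collapsed read stacks.

    ``precision`` is the fraction of each miRNA locus's reads whose 5' ends
    sit exactly on the planted mature/star 5' ends (mature gets
    ``mature_share`` of the signal). The remainder are offset reads from
    random precursor positions. siRNA loci emit dispersed 24-mers; the
    leftover depth is genome-wide background. Counts per locus are negative
    binomial around depth x fraction x locus weight (variance
    mu + dispersion * mu^2).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not (0.75 <= precision <= 1.0):
        raise ValueError("precision must be in [0.75, 1]")
    rng = np.random.default_rng(seed)
    counter: Counter[str] = Counter()

    def nb(mean: float) -> int:
        if mean <= 0:
            return 0
        r = 1.0 / dispersion
        return int(rng.negative_binomial(r, r / (r + mean)))

    weights = locus_weights(truth, tissue=tissue)
    wsum = sum(weights.values())
    for pm in truth.planted_mirna_loci:
        n_loc = nb(depth * mirna_fraction * weights[pm.locus_id] / wsum)
        if n_loc == 0:
            continue
        n_signal = int(rng.binomial(n_loc, precision))
        n_mat = int(rng.binomial(n_signal, mature_share))
        counter[pm.mature_seq] += n_mat
        counter[pm.star_seq] += n_signal - n_mat
        pre = pm.precursor_seq
        for _ in range(n_loc - n_signal):
            ln = int(rng.integers(20, 25))
            start = int(rng.integers(0, len(pre) - ln + 1))
            counter[pre[start:start + ln]] += 1

    for iv in truth.planted_sirna_loci:
        n_loc = nb(depth * sirna_fraction / max(1, len(truth.planted_sirna_loci)))
        seq = genome[iv.chrom][iv.start:iv.end]
        for _ in range(n_loc):
            start = int(rng.integers(0, len(seq) - 24 + 1))
            read = seq[start:start + 24]
            counter[read if rng.random() < 0.5 else revcomp(read)] += 1

    n_bg = nb(depth * max(0.0, 1.0 - mirna_fraction - sirna_fraction))
    chroms = sorted(genome)
    for _ in range(n_bg):
        c = chroms[int(rng.integers(0, len(chroms)))]
        ln = int(rng.integers(18, 29))
        start = int(rng.integers(0, len(genome[c]) - ln + 1))
        read = genome[c][start:start + ln]
        counter[read if rng.random() < 0.5 else revcomp(read)] += 1

    return [ReadStack(seq, {library_id: n})
            for seq, n in sorted(counter.items())]


# ------------------------------------------------------------- transcriptome


def generate_transcriptome(
    truth: TruthSet,
    n_background: int = 30,
    transcript_length: int = 800,
    targets_per_mirna: int = 1,
    seed: int = 0,
) -> tuple[dict[str, str], TruthSet]:
    """Transcripts carrying one perfect-complement target site per planted
    pair, plus background transcripts with no site. Replaces (not appends)
    ``truth.planted_target_pairs`` and returns the updated truth."""
    rng = np.random.default_rng(seed)
    truth.planted_target_pairs = []
    transcripts: dict[str, str] = {}
    ti = 0
    for pm in truth.planted_mirna_loci:
        for _ in range(targets_per_mirna):
            ti += 1
            tid = f"tx{ti:04d}"
            site = revcomp(pm.mature_seq)
            m = len(site)
            start = int(rng.integers(50, transcript_length - m - 50))
            seq = _rand_seq(rng, transcript_length)
            seq = seq[:start] + site + seq[start + m:]
            transcripts[tid] = seq
            truth.planted_target_pairs.append(PlantedTarget(
                mirna_id=pm.locus_id, transcript_id=tid,
                site_start=start, cleavage_pos=start + m - 9))
    for _ in range(n_background):
        ti += 1
        transcripts[f"tx{ti:04d}"] = _rand_seq(rng, transcript_length)
    return transcripts, truth


def generate_degradome_library(
    truth: TruthSet,
    transcriptome: dict[str, str],
    signal_reads: int = 50,
    noise_reads: int = 0,
    seed: int = 0,
) -> dict[str, dict[int, int]]:
    """Per-transcript 5'-end count table: ``signal_reads`` at each planted
    cleavage position, ``noise_reads`` spread uniformly over all positions."""
    rng = np.random.default_rng(seed)
    density: dict[str, dict[int, int]] = {tx: {} for tx in transcriptome}
    for pt in truth.planted_target_pairs:
        if pt.transcript_id not in transcriptome:
            raise ValueError(f"unknown transcript {pt.transcript_id}")
        if signal_reads > 0:
            d = density[pt.transcript_id]
            d[pt.cleavage_pos] = d.get(pt.cleavage_pos, 0) + signal_reads
    if noise_reads > 0:
        txs = sorted(transcriptome)
        lens = np.array([len(transcriptome[t]) for t in txs])
        choice_tx = rng.choice(len(txs), size=noise_reads, p=lens / lens.sum())
        for i in choice_tx:
            pos = int(rng.integers(1, lens[i] + 1))
            d = density[txs[i]]
            d[pos] = d.get(pos, 0) + 1
    return {tx: d for tx, d in density.items() if d}


# --------------------------------------------------------- expression truth


def generate_expression_profiles(
    truth: TruthSet,
    n_tissues: int = 4,
    n_reps: int = 2,
    negative_fraction: float = 0.46,
    noise_sd: float = 0.05,
    seed: int = 0,
    sigma_log: float = 1.5,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """miRNA (RPM) and transcript (FPKM) matrices over tissues x replicates.

    An exact ``round(negative_fraction * n_pairs)`` subset of the planted
    target pairs gets a target tissue profile that is an affine negative
    transform of its miRNA profile (Pearson r over tissue means = -1 at
    ``noise_sd`` = 0); the remaining targets are independent. Chosen pairs
    are recorded in ``truth.planted_negative_pairs``.
    """
    if not (0.0 <= negative_fraction <= 1.0):
        raise ValueError("negative_fraction outside [0,1]")
    if n_tissues < 3:
        raise ValueError("need >= 3 tissues for Pearson over tissue means")
    rng = np.random.default_rng(seed)
    tissues = [f"T{i+1}" for i in range(n_tissues)]
    samples = {f"{t}.R{r+1}": (t, f"R{r+1}")
               for t in tissues for r in range(n_reps)}

    mirna_ids = [pm.locus_id for pm in truth.planted_mirna_loci]
    mir_profiles = {mid: rng.lognormal(3.0, sigma_log, n_tissues)
                    for mid in mirna_ids}

    pairs = list(truth.planted_target_pairs)
    n_neg = int(round(negative_fraction * len(pairs)))
    neg_idx = set(rng.choice(len(pairs), size=n_neg, replace=False).tolist()) \
        if n_neg else set()
    truth.planted_negative_fraction = negative_fraction
    truth.planted_negative_pairs = {
        (pairs[i].mirna_id, pairs[i].transcript_id) for i in neg_idx}

    tx_profiles: dict[str, np.ndarray] = {}
    for i, pt in enumerate(pairs):
        if i in neg_idx:
            mp = mir_profiles[pt.mirna_id]
            scale = float(rng.uniform(0.5, 2.0))
            tx_profiles[pt.transcript_id] = scale * (mp.max() + mp.min() - mp)
        else:
            tx_profiles.setdefault(pt.transcript_id,
                                   rng.lognormal(3.0, sigma_log, n_tissues))

    def build(profiles: dict[str, np.ndarray], unit: str) -> ExpressionMatrix:
        data = {}
        for sid, (t, _r) in samples.items():
            ti = tissues.index(t)
            col = np.array([profiles[e][ti] for e in profiles])
            if noise_sd > 0:
                col = np.maximum(0.0, col * (1 + rng.normal(0, noise_sd, len(col))))
            data[sid] = col
        df = pd.DataFrame(data, index=list(profiles))
        return ExpressionMatrix(df, samples, unit)

    return build(mir_profiles, "RPM"), build(tx_profiles, "FPKM")


# --------------------------------------------------------------- TF inputs


def generate_tf_motifs_and_promoters(
    n_tfs: int = 5,
    n_sites: int = 20,
    motif_length: int = 8,
    n_promoters: int = 10,
    promoter_length: int = 2000,
    seed: int = 0,
    consensus_weight: float = 0.85,
) -> tuple[list[Pwm], dict[str, str], list[tuple[str, str, int]]]:
    """PWMs, promoter FASTA sequences and planted (tf, promoter, offset) sites.

    Each planted site is the exact consensus of its PWM written at the
    recorded offset; sites never overlap within a promoter.
    """
    if motif_length < 6:
        raise ValueError("motif_length must be >= 6")
    capacity = n_promoters * (promoter_length // (2 * motif_length))
    if n_sites > capacity:
        raise ValueError(f"{n_sites} sites exceed promoter capacity {capacity}")
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n_tfs):
        consensus = _rand_seq(rng, motif_length)
        mat = np.full((motif_length, 4), (1 - consensus_weight) / 3)
        for p, b in enumerate(consensus):
            mat[p, "ACGT".index(b)] = consensus_weight
        pwms.append(Pwm(f"TF{i+1:02d}", mat))

    promoters = {f"prom{i+1:03d}": _rand_seq(rng, promoter_length)
                 for i in range(n_promoters)}
    occupied: dict[str, list[tuple[int, int]]] = {p: [] for p in promoters}
    sites: list[tuple[str, str, int]] = []
    prom_ids = sorted(promoters)
    attempts = 0
    while len(sites) < n_sites:
        attempts += 1
        if attempts > 100 * n_sites:
            raise ValueError("could not place all sites without overlap")
        pwm = pwms[int(rng.integers(0, n_tfs))]
        pid = prom_ids[int(rng.integers(0, n_promoters))]
        off = int(rng.integers(0, promoter_length - motif_length + 1))
        if any(off < e and s < off + motif_length for s, e in occupied[pid]):
            continue
        occupied[pid].append((off, off + motif_length))
        seq = promoters[pid]
        promoters[pid] = seq[:off] + pwm.consensus + seq[off + motif_length:]
        sites.append((pwm.tf_id, pid, off))
    return pwms, promoters, sites


# ------------------------------------------------------- reference catalog


def generate_reference_catalog(
    truth: TruthSet,
    focal_clade: str = "Asteraceae",
    seed: int = 0,
    p_conserved: float = 0.5,
    p_clade: float = 0.2,
):
    """A reference mature-miRNA catalog inducing known conservation classes.

    Families are assigned a class: conserved families get catalog entries
    in a non-focal clade (plus optionally the focal clade), clade-specific
    families only in other focal-clade species, the rest are absent. The
    per-locus expectation is recorded in ``truth.planted_conservation``.
    """
    from .conservation import CatalogEntry, ReferenceCatalog
    rng = np.random.default_rng(seed)
    clade_map = {"speciesX": "OtherClade", "speciesY": focal_clade,
                 "speciesZ": "ThirdClade"}
    entries = []
    fam_class: dict[str, str] = {}
    ei = 0
    for pm in truth.planted_mirna_loci:
        fam = pm.family
        if fam not in fam_class:
            u = rng.random()
            fam_class[fam] = ("conserved" if u < p_conserved else
                              "clade_specific" if u < p_conserved + p_clade
                              else "species_specific")
            if fam_class[fam] == "conserved":
                ei += 1
                entries.append(CatalogEntry(pm.mature_seq, f"ref-mir-{ei}", "speciesX"))
            elif fam_class[fam] == "clade_specific":
                ei += 1
                entries.append(CatalogEntry(pm.mature_seq, f"ref-mir-{ei}", "speciesY"))
        truth.planted_conservation[pm.locus_id] = fam_class[fam]
    return ReferenceCatalog(entries, clade_map, focal_clade)


# ---------------------------------------------------------- synteny anchors


def generate_anchor_table(
    n_blocks: int = 3,
    anchors_per_block: int = 8,
    n_noise: int = 10,
    genes_per_chrom: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[list[tuple[str, str]]]]:
    """A homolog-pair anchor table with planted collinear blocks.

    Genes sit at ordinal ranks on two chromosomes; each planted block maps
    ``anchors_per_block`` consecutive ranks on chrA to consecutive
    (ascending or descending) ranks on chrB. Noise anchors are random
    pairs. Returns (anchor DataFrame, planted anchor-pair lists).
    """
    rng = np.random.default_rng(seed)
    rows = []
    planted: list[list[tuple[str, str]]] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    span = anchors_per_block * 2
    for b in range(n_blocks):
        while True:
            sa = int(rng.integers(0, genes_per_chrom - span))
            sb = int(rng.integers(0, genes_per_chrom - span))
            ra = set(range(sa, sa + span))
            rb = set(range(sb, sb + span))
            if not (ra & used_a) and not (rb & used_b):
                used_a |= ra
                used_b |= rb
                break
        inverted = rng.random() < 0.5
        block_pairs = []
        for k in range(anchors_per_block):
            ga = sa + 2 * k
            gb = sb + 2 * (anchors_per_block - 1 - k) if inverted else sb + 2 * k
            rows.append(("chrA", f"gA{ga:04d}", ga, "chrB", f"gB{gb:04d}", gb))
            block_pairs.append((f"gA{ga:04d}", f"gB{gb:04d}"))
        planted.append(block_pairs)
    for _ in range(n_noise):
        ga = int(rng.integers(0, genes_per_chrom))
        gb = int(rng.integers(0, genes_per_chrom))
        if ga in used_a or gb in used_b:
            continue
        rows.append(("chrA", f"gA{ga:04d}", ga, "chrB", f"gB{gb:04d}", gb))
    df = pd.DataFrame(rows, columns=["chrom_a", "gene_a", "rank_a",
                                     "chrom_b", "gene_b", "rank_b"])
    return df, planted
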