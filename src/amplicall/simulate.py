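"""Synthetic amplicon sequencing data with known ground truth.

Emulates deep sequencing of single-cell clones edited at one locus: each
clone is a mixture of a few allele haplotypes (reference with 0-n indels
near a cut site), sequenced to tens of thousands of reads. The error model
is substitution-dominated (random polymerase/sequencer point errors at a
per-base rate) with rare spurious 1-bp indels per read; this is what lets
tests confirm that the read-count cutoff — not the aligner — removes
artifact genotypes. Qualities are constant high ('I'): the pipeline only
consults quality at pair-merge mismatches, so realism there buys nothing.

All randomness flows through a single seed; identical specs produce
byte-identical FASTQ output.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._dna import revcomp
from .errors import SimSpecError
from .genotyping import GenotypeSignature, IndelVariant, RawIndel, left_normalize
from .reference_io import ReferenceRegion

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: The "paper-scale" cohort preset: publication-depth sequencing of 20
#: clones at 50,000-70,000 reads each, 2-4 alleles per clone with one
#: 10-allele outlier, indels concentrated at the cut site; substitution
#: errors at 0.3 % per base and spurious 1-bp indels on 0.5 % of reads.
PAPER_SCALE = dict(
    n_clones=20,
    reads_range=(50_000, 70_000),
    alleles_range=(2, 4),
    outlier_clone_alleles=10,
    error_rate=0.003,
    error_indel_rate=0.005,
)


@dataclass(frozen=True)
class SimSpec:
    """Recipe for one simulated clone.

    ``alleles`` maps signatures to target proportions (positive, summing to
    <= 1; any remainder becomes uniformly random junk reads). ``read_length``
    None means single-end reads spanning the whole haplotype, as in amplicon
    sequencing with read length >= amplicon; paired mode emits overlapping
    R1/R2 mates of ``read_length`` each.
    """

    region: ReferenceRegion
    alleles: tuple[tuple[GenotypeSignature, float], ...]
    n_reads: int = 50_000
    error_rate: float = 0.003
    error_indel_rate: float = 0.005
    read_length: Optional[int] = None
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        total = 0.0
        for sig, p in self.alleles:
            if p <= 0:
                raise SimSpecError(f"allele proportion must be positive, got {p}")
            total += p
        if total > 1.0 + 1e-9:
            raise SimSpecError(f"allele proportions sum to {total} > 1")
        if self.n_reads < 0 or self.error_rate < 0 or self.error_indel_rate < 0:
            raise SimSpecError("negative read count or error rate")


@dataclass
class SimResult:
    """What a simulation produced: file paths plus the realized truth."""

    fastq_paths: list[Path]
    truth_path: Optional[Path]
    allele_signatures: list[GenotypeSignature]
    target_proportions: list[float]
    realized_counts: list[int]  # per allele; junk count appended last
    n_reads: int


# ---------------------------------------------------------------------------
# Haplotype construction
# ---------------------------------------------------------------------------


def apply_signature(region: ReferenceRegion, sig: GenotypeSignature) -> str:
    """Edited haplotype: region sequence with the signature's indels applied.

    Variants are applied right-to-left (descending position) so earlier
    coordinates stay valid; overlapping variants are an error. Applying the
    empty signature returns the region sequence itself, and the REF field of
    every variant is checked against the region before substitution.
    """
    seq = region.sequence
    ordered = sorted(sig.variants, key=lambda v: v.pos, reverse=True)
    prev_start: Optional[int] = None
    for v in ordered:
        lo, hi = v.footprint()
        if prev_start is not None and hi >= prev_start:
            raise SimSpecError(f"overlapping variants in signature {sig.key}")
        prev_start = lo
        i = region.genomic_to_local(v.pos) - 1  # 0-based anchor offset
        ref_here = region.sequence[i : i + len(v.ref)]
        if ref_here != v.ref:
            raise SimSpecError(
                f"variant {v.key}: REF {v.ref!r} does not match region ({ref_here!r})"
            )
        seq = seq[:i] + v.alt + seq[i + len(v.ref) :]
    return seq


def deletion_variant(region: ReferenceRegion, local_start: int, length: int) -> IndelVariant:
    """Left-normalized deletion of ``length`` bases starting at 1-based local position."""
    seq = region.sequence[local_start - 1 : local_start - 1 + length]
    return left_normalize(RawIndel("deletion", local_start, seq), region)


def insertion_variant(region: ReferenceRegion, local_before: int, ins: str) -> IndelVariant:
    """Left-normalized insertion of ``ins`` before 1-based local position."""
    return left_normalize(RawIndel("insertion", local_before, ins), region)


def random_region(
    length: int = 296,
    seed: int = 0,
    chrom: str = "chrS",
    start: int = 1000,
    genome_label: str = "synthetic",
) -> ReferenceRegion:
    """A random amplicon-scale reference window (synthetic stand-in genome)."""
    rng = np.random.default_rng(seed)
    seq = bytes(_BASES[rng.integers(0, 4, size=length)]).decode()
    return ReferenceRegion(chrom, start, start + length - 1, seq, genome_label)


def random_signature(
    region: ReferenceRegion,
    rng: np.random.Generator,
    cut_site_local: Optional[int] = None,
    allow_wt: bool = False,
) -> GenotypeSignature:
    """One plausible editing outcome near the cut site.

    Mimics the repair spectrum after a double-strand break: mostly small
    deletions (1-15 bp, with 1-3 and 12-15 both common), occasional small
    insertions (1-3 bp), starting within ~10 bp of the cut.
    """
    cut = cut_site_local if cut_site_local is not None else len(region) // 2
    if allow_wt and rng.random() < 0.1:
        return GenotypeSignature()
    start = int(np.clip(cut + rng.integers(-10, 11), 2, len(region) - 20))
    if rng.random() < 0.9:
        length = int(rng.choice([1, 2, 3, 12, 13, 14, 15, 5, 8]))
        return GenotypeSignature((deletion_variant(region, start, length),))
    length = int(rng.integers(1, 4))
    ins = bytes(_BASES[rng.integers(0, 4, size=length)]).decode()
    return GenotypeSignature((insertion_variant(region, start, ins),))


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------


def _mutate_reads(
    haplotype: str, n: int, error_rate: float, indel_rate: float, rng: np.random.Generator
) -> list[str]:
    """n reads of one allele with substitution and spurious 1-bp indel errors."""
    L = len(haplotype)
    base = np.frombuffer(haplotype.encode(), dtype=np.uint8)
    n_subs = rng.binomial(L, error_rate, size=n) if error_rate > 0 else np.zeros(n, int)
    has_indel = (
        rng.random(n) < indel_rate if indel_rate > 0 else np.zeros(n, bool)
    )
    reads: list[str] = []
    for k in range(n):
        if n_subs[k] == 0 and not has_indel[k]:
            reads.append(haplotype)
            continue
        arr = base.copy()
        if n_subs[k] > 0:
            pos = rng.choice(L, size=n_subs[k], replace=False)
            for p in pos:
                choices = _BASES[_BASES != arr[p]]
                arr[p] = rng.choice(choices)
        seq = bytes(arr).decode()
        if has_indel[k]:
            p = int(rng.integers(0, len(seq)))
            if rng.random() < 0.5 and len(seq) > 1:
                seq = seq[:p] + seq[p + 1 :]  # spurious 1-bp deletion
            else:
                b = chr(_BASES[rng.integers(0, 4)])
                seq = seq[:p] + b + seq[p:]  # spurious 1-bp insertion
        reads.append(seq)
    return reads


def _write_fastq(path: Path, reads: Sequence[str]) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@r{i:07d}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_clone_fastq(spec: SimSpec, out_path: str | Path) -> SimResult:
    """Simulate one clone's FASTQ (single- or paired-end) plus a truth table.

    Each read's allele is drawn from the categorical target proportions
    (multinomial); the truth table records signatures, targets and realized
    counts. ``out_path`` is the FASTQ path for single-end data; paired mode
    derives ``_R1``/``_R2`` names from it.
    """
    out_path = Path(out_path)
    rng = np.random.default_rng(spec.seed)
    haplotypes = [apply_signature(spec.region, sig) for sig, _ in spec.alleles]
    if spec.read_length is not None and not spec.paired:
        too_long = [h for h in haplotypes if len(h) > spec.read_length]
        if too_long:
            raise SimSpecError(
                f"read_length {spec.read_length} shorter than a haplotype "
                f"({max(len(h) for h in haplotypes)} bp); single-end reads must span the amplicon"
            )
    if spec.paired:
        if spec.read_length is None:
            raise SimSpecError("paired mode requires read_length")
        min_hap = min((len(h) for h in haplotypes), default=0)
        if haplotypes and 2 * spec.read_length - max(len(h) for h in haplotypes) < 6:
            raise SimSpecError(
                "mates too short to overlap: need 2*read_length >= haplotype + 6"
            )
        del min_hap
    probs = [p for _, p in spec.alleles]
    junk_p = max(0.0, 1.0 - sum(probs))
    counts = rng.multinomial(spec.n_reads, probs + [junk_p])
    fragments: list[str] = []
    for hap, n in zip(haplotypes, counts[:-1]):
        fragments.extend(
            _mutate_reads(hap, int(n), spec.error_rate, spec.error_indel_rate, rng)
        )
    for _ in range(int(counts[-1])):
        L = len(spec.region)
        fragments.append(bytes(_BASES[rng.integers(0, 4, size=L)]).decode())
    order = rng.permutation(len(fragments))
    fragments = [fragments[i] for i in order]

    out_path.parent.mkdir(parents=True, exist_ok=True)
    if spec.paired:
        rl = spec.read_length
        r1 = [f[:rl] for f in fragments]
        r2 = [revcomp(f[-rl:]) for f in fragments]
        name = out_path.name
        for suf in (".fastq.gz", ".fq.gz", ".fastq", ".fq"):
            if name.endswith(suf):
                stem, ext = name[: -len(suf)], suf
                break
        else:
            stem, ext = name, ".fastq"
        p1 = out_path.parent / f"{stem}_R1{ext}"
        p2 = out_path.parent / f"{stem}_R2{ext}"
        _write_fastq(p1, r1)
        _write_fastq(p2, r2)
        fastq_paths = [p1, p2]
        truth_base = out_path.parent / f"{stem}.truth.tsv"
    else:
        _write_fastq(out_path, fragments)
        fastq_paths = [out_path]
        base = out_path.name
        for suf in (".fastq.gz", ".fq.gz", ".fastq", ".fq"):
            if base.endswith(suf):
                base = base[: -len(suf)]
                break
        truth_base = out_path.parent / f"{base}.truth.tsv"
    lines = ["allele_id\tsignature\ttarget_proportion\trealized_count"]
    for i, ((sig, p), n) in enumerate(zip(spec.alleles, counts[:-1])):
        lines.append(f"A{i + 1}\t{sig.key}\t{p:.6f}\t{int(n)}")
    lines.append(f"junk\tNA\t{junk_p:.6f}\t{int(counts[-1])}")
    truth_base.write_text("\n".join(lines) + "\n")
    return SimResult(
        fastq_paths=fastq_paths,
        truth_path=truth_base,
        allele_signatures=[sig for sig, _ in spec.alleles],
        target_proportions=probs,
        realized_counts=[int(c) for c in counts],
        n_reads=spec.n_reads,
    )


# ---------------------------------------------------------------------------
# Cohort presets
# ---------------------------------------------------------------------------


@dataclass
class CohortResult:
    region: ReferenceRegion
    clones: dict[str, SimResult] = field(default_factory=dict)
    fastq_dir: Optional[Path] = None


def simulate_cohort(
    out_dir: str | Path,
    seed: int = 0,
    preset: str = "paper-scale",
    region: Optional[ReferenceRegion] = None,
    n_clones: Optional[int] = None,
    reads_range: Optional[tuple[int, int]] = None,
    shared_pool_size: int = 12,
) -> CohortResult:
    """Simulate a cohort of edited single-cell clones into one directory.

    The ``paper-scale`` preset: clones of 50,000-70,000 reads, 2-4 alleles
    each with one 10-allele outlier clone, allele signatures drawn from a
    shared pool so some genotypes recur across clones (as happens when
    independent clones repair the same cut the same way).
    """
    if preset != "paper-scale":
        raise SimSpecError(f"unknown preset {preset!r}")
    cfg = PAPER_SCALE
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if region is None:
        region = random_region(seed=int(rng.integers(0, 2**31 - 1)))
    nc = n_clones if n_clones is not None else cfg["n_clones"]
    rr = reads_range if reads_range is not None else cfg["reads_range"]
    pool: list[GenotypeSignature] = []
    seen: set[str] = set()
    while len(pool) < shared_pool_size:
        sig = random_signature(region, rng)
        if sig.key not in seen:
            seen.add(sig.key)
            pool.append(sig)
    result = CohortResult(region=region, fastq_dir=out_dir)
    outlier = int(rng.integers(0, nc)) if nc >= 6 else -1
    for c in range(nc):
        sample = f"S{c + 1}"
        k = cfg["outlier_clone_alleles"] if c == outlier else int(
            rng.integers(cfg["alleles_range"][0], cfg["alleles_range"][1] + 1)
        )
        chosen: list[GenotypeSignature] = []
        keys: set[str] = set()
        while len(chosen) < k:
            if rng.random() < 0.5 and pool:
                sig = pool[int(rng.integers(0, len(pool)))]
            else:
                sig = random_signature(region, rng)
            if sig.key not in keys:
                keys.add(sig.key)
                chosen.append(sig)
        weights = rng.dirichlet(np.full(k, 8.0))
        weights = 0.97 * weights / weights.sum()  # leave ~3 % junk reads
        spec = SimSpec(
            region=region,
            alleles=tuple(zip(chosen, (float(w) for w in weights))),
            n_reads=int(rng.integers(rr[0], rr[1] + 1)),
            error_rate=cfg["error_rate"],
            error_indel_rate=cfg["error_indel_rate"],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        result.clones[sample] = simulate_clone_fastq(spec, out_dir / f"{sample}.fastq")
    ref_path = out_dir / "reference.fasta"
    pad = "".join("ACGT"[i % 4] for i in range(region.start - 1))
    ref_path.write_text(f">{region.chrom}\n{pad}{region.sequence}\n")
    return result
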