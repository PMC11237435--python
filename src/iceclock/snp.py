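"""Pileup construction, fixed-difference SNP calling and rate calibration.

Reads aligned against a (possibly multi-contig, concatenated) reference are
collapsed into per-position base counts; positions where the sample's reads
near-unanimously carry a non-reference base are called as fixed-difference
SNPs, and the count is converted into a rate in SNPs per Mb per century
together with a read-based average nucleotide identity (ANIg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam
from Bio import SeqIO

from .errors import MalformedRecordError, UndefinedRateError

BASES = "ACGT"
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i

# CIGAR op codes (pysam numeric): M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_QUERY_CONSUMING = {0, 1, 4, 7, 8}


@dataclass(frozen=True)
class ReferenceGenome:
    """Concatenated reference: contigs laid end to end in input order."""

    name: str
    sequence: str  # uppercase A/C/G/T/N
    contigs: tuple  # ((contig_name, length), ...) in concatenation order
    offsets: dict  # contig_name -> 0-based offset into `sequence`

    @property
    def length(self) -> int:
        return len(self.sequence)

    def global_to_contig(self, pos: int) -> tuple:
        """Map a concatenated 0-based position to (contig_name, local_pos)."""
        for cname, clen in self.contigs:
            off = self.offsets[cname]
            if off <= pos < off + clen:
                return cname, pos - off
        raise IndexError(f"position {pos} outside reference of length {self.length}")


def reference_from_sequence(sequence: str, name: str = "ref") -> ReferenceGenome:
    """Wrap a single plain sequence as a one-contig reference."""
    seq = sequence.upper()
    return ReferenceGenome(
        name=name, sequence=seq, contigs=((name, len(seq)),), offsets={name: 0}
    )


def read_reference(path, name=None) -> ReferenceGenome:
    """Load a FASTA file and concatenate its contigs in file order."""
    contigs = []
    offsets = {}
    parts = []
    offset = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        contigs.append((rec.id, len(seq)))
        offsets[rec.id] = offset
        parts.append(seq)
        offset += len(seq)
    if not parts:
        raise ValueError(f"no sequences found in {path}")
    return ReferenceGenome(
        name=name or contigs[0][0],
        sequence="".join(parts),
        contigs=tuple(contigs),
        offsets=offsets,
    )


@dataclass
class Pileup:
    """Per-position base counts over the concatenated reference."""

    ref: ReferenceGenome
    counts: np.ndarray  # (L, 4) int32, columns ordered A,C,G,T

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def ref_index(self) -> np.ndarray:
        """Reference base as 0..3 index (255 for N/ambiguous)."""
        arr = np.frombuffer(self.ref.sequence.encode("ascii"), dtype=np.uint8)
        return _BASE_LUT[arr]


@dataclass(frozen=True)
class SnpCall:
    """A biallelic fixed-difference substitution call."""

    position: int  # 0-based on the concatenated reference
    ref: str
    alt: str
    alt_freq: float
    depth: int


@dataclass(frozen=True)
class RateEstimate:
    """SNP count converted to a rate plus read-based nucleotide identity."""

    snp_count: int
    mapped_length: int  # bp
    elapsed: float  # yr
    rate: float  # SNPs per Mb per century
    ani: float  # percent


def build_pileup(ref: ReferenceGenome, sam_path) -> Pileup:
    """Accumulate base counts by walking each record's CIGAR.

    M/=/X ops consume reference and read and increment counts; D/N consume
    reference only; I/S consume read only; H and P consume neither.
    Unmapped and secondary records are skipped.

    Raises
    ------
    MalformedRecordError
        If a record's CIGAR query length disagrees with its sequence length
        (the message names the read).
    """
    counts = np.zeros((ref.length, 4), dtype=np.int32)
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        records = _iter_records(sam, sam_path)
        for aln in records:
            if aln.is_unmapped or aln.is_secondary:
                continue
            if aln.reference_name not in ref.offsets:
                raise MalformedRecordError(
                    f"read {aln.query_name!r}: unknown reference "
                    f"{aln.reference_name!r}"
                )
            seq = aln.query_sequence
            cig = aln.cigartuples
            if seq is None or cig is None:
                raise MalformedRecordError(
                    f"read {aln.query_name!r}: missing sequence or CIGAR"
                )
            qlen = sum(n for op, n in cig if op in _QUERY_CONSUMING and op != 5)
            if qlen != len(seq):
                raise MalformedRecordError(
                    f"read {aln.query_name!r}: CIGAR consumes {qlen} query bases "
                    f"but sequence has {len(seq)}"
                )
            qarr = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            rpos = ref.offsets[aln.reference_name] + aln.reference_start
            qpos = 0
            for op, n in cig:
                if op in (0, 7, 8):  # M, =, X
                    sub = qarr[qpos : qpos + n]
                    valid = sub < 4
                    idx = rpos + np.nonzero(valid)[0]
                    np.add.at(counts, (idx, sub[valid]), 1)
                    rpos += n
                    qpos += n
                elif op in (2, 3):  # D, N
                    rpos += n
                elif op in (1, 4):  # I, S
                    qpos += n
                # H (5), P (6): consume neither
    return Pileup(ref=ref, counts=counts)


_CIGAR_QUERY_OPS = frozenset("MIS=X")


def _iter_records(sam, sam_path):
    """Yield records, converting htslib parse failures into package errors."""
    while True:
        try:
            yield next(sam)
        except StopIteration:
            return
        except OSError as exc:
            raise _malformed_error(sam_path) from exc


def _malformed_error(sam_path) -> MalformedRecordError:
    """Rescan the SAM text to name the record htslib choked on."""
    import re

    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10 or f[5] == "*" or f[9] == "*":
                continue
            qlen = sum(
                int(n)
                for n, op in re.findall(r"(\d+)([MIDNSHP=X])", f[5])
                if op in _CIGAR_QUERY_OPS
            )
            if qlen != len(f[9]):
                return MalformedRecordError(
                    f"read {f[0]!r}: CIGAR consumes {qlen} query bases but "
                    f"sequence has {len(f[9])}"
                )
    return MalformedRecordError(f"unparseable SAM record in {sam_path}")


def call_snps(pileup: Pileup, min_depth: int = 5, min_alt_freq: float = 0.9) -> list:
    """Call fixed-difference substitutions from a pileup.

    A position is called when its depth is at least ``min_depth`` and the
    most frequent non-reference base reaches ``min_alt_freq`` of the depth.
    Positions whose reference base is N are excluded.
    """
    if not (0 < min_alt_freq <= 1):
        raise ValueError("min_alt_freq must be in (0, 1]")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depth = pileup.depth
    ridx = pileup.ref_index
    alt_counts = pileup.counts.copy()
    known = ridx < 4
    rows = np.nonzero(known)[0]
    alt_counts[rows, ridx[rows]] = 0
    best_alt = alt_counts.argmax(axis=1)
    best_n = alt_counts[np.arange(len(alt_counts)), best_alt]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, best_n / np.maximum(depth, 1), 0.0)
    mask = known & (depth >= min_depth) & (freq >= min_alt_freq) & (best_n > 0)
    calls = []
    for pos in np.nonzero(mask)[0]:
        calls.append(
            SnpCall(
                position=int(pos),
                ref=BASES[ridx[pos]],
                alt=BASES[best_alt[pos]],
                alt_freq=float(freq[pos]),
                depth=int(depth[pos]),
            )
        )
    return calls


def mapped_region_length(pileup: Pileup, min_depth: int = 5) -> tuple:
    """Number of reference positions with depth >= ``min_depth`` and the
    corresponding fraction of the genome."""
    n = int(np.count_nonzero(pileup.depth >= min_depth))
    return n, n / pileup.ref.length


def snp_rate(snp_count: int, mapped_length: int, elapsed: float) -> RateEstimate:
    """Convert a SNP count into SNPs per Mb per century plus ANIg (%).

    ``rate = snp_count / (mapped_length / 1e6) / (elapsed / 100)``;
    ``ani = 100 * (1 - snp_count / mapped_length)``.
    """
    if mapped_length <= 0:
        raise UndefinedRateError("mapped_length must be positive")
    if elapsed <= 0:
        raise UndefinedRateError("elapsed must be positive")
    rate = snp_count / (mapped_length / 1e6) / (elapsed / 100.0)
    ani = 100.0 * (1.0 - snp_count / mapped_length)
    return RateEstimate(
        snp_count=int(snp_count),
        mapped_length=int(mapped_length),
        elapsed=float(elapsed),
        rate=float(rate),
        ani=float(ani),
    )


def write_vcf(calls, ref: ReferenceGenome, path) -> None:
    """Write calls as minimal VCF (CHROM, 1-based POS, REF, ALT, DP/AF)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            '##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele frequency">\n'
        )
        for cname, clen in ref.contigs:
            fh.write(f"##contig=<ID={cname},length={clen}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            chrom, local = ref.global_to_contig(c.position)
            fh.write(
                f"{chrom}\t{local + 1}\t.\t{c.ref}\t{c.alt}\t.\t.\t"
                f"DP={c.depth};AF={c.alt_freq:.4f}\n"
            )
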