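"""Synthetic inputs with known ground truth for every pipeline stage.

Provides analytic velocity fields (with exact strain rates), flowline
segment series with closed-form thickness/age solutions, random genomes,
time-evolved descendants with planted substitutions at a controlled
per-site rate, and simulated reads with exact truth alignments — so the
full pipeline is testable without any external dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .flowline import FlowlineSegment, VelocityField
from .molevo import CODON_TO_AA, STOP_CODONS
from .snp import ReferenceGenome, reference_from_sequence

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


# ---------------------------------------------------------------------------
# velocity fields


def make_velocity_field(kind: str, k: float, grid=None):
    """Analytic velocity field sampled on a grid, with its exact strain rate.

    Kinds: ``uniform`` (u=k, v=0), ``divergent`` (u=kx, v=0) and
    ``rotational`` (u=-ky, v=kx).  Returns ``(VelocityField, strain_fn)``
    where ``strain_fn(x, y)`` is the exact vertical strain rate
    ``-(du/dx + dv/dy)``.

    ``grid`` is ``(x_coords, y_coords)``; default a 41x41 grid on
    [-2000, 2000] m.
    """
    if grid is None:
        x = np.linspace(-2000.0, 2000.0, 41)
        y = np.linspace(-2000.0, 2000.0, 41)
    else:
        x, y = (np.asarray(g, dtype=float) for g in grid)
    xx, yy = np.meshgrid(x, y)
    if kind == "uniform":
        u, v = np.full_like(xx, k), np.zeros_like(xx)
        strain = lambda px, py: 0.0
    elif kind == "divergent":
        u, v = k * xx, np.zeros_like(xx)
        strain = lambda px, py: -k
    elif kind == "rotational":
        u, v = -k * yy, k * xx
        strain = lambda px, py: 0.0
    else:
        raise ConfigurationError(f"unknown velocity field kind {kind!r}")
    return VelocityField(x=x, y=y, u=u, v=v), strain


# ---------------------------------------------------------------------------
# ice scenarios


@dataclass(frozen=True)
class IceScenario:
    """Named synthetic forcing scenario for the layer model."""

    name: str  # constant_accretion | steady_strain | accretion_with_melt_episode | paper_like
    accretion_rate: float = 0.5  # a, m/yr (magnitude of basal freezing)
    strain_rate: float = 0.0  # epsilon, 1/yr (magnitude of thinning)
    total_time: float = 100.0  # yr
    dt: float = 1.0  # yr per segment
    melt_episode: tuple = None  # (t_start, t_end, melt_rate m/yr)
    sigma_ab: float = 0.0  # 1-sigma basal-rate uncertainty, m/yr
    seed: int = 0


@dataclass(frozen=True)
class SegmentSeries:
    """Segments plus whatever closed-form solution the scenario admits."""

    scenario: IceScenario
    segments: tuple
    closed_form_thickness: object = None  # callable t -> Hm(t), or None
    closed_form_age: object = None  # callable depth -> age, or None


def make_segments(scenario: IceScenario) -> SegmentSeries:
    """Build a deterministic segment series for a named scenario.

    ``constant_accretion``: ab = -a throughout, no strain; closed form
    ``Hm(t) = a t`` with ages linear in depth.
    ``steady_strain``: ab = -a, ezz = -eps; closed form
    ``Hm(t) = (a/eps)(1 - exp(-eps t))``.
    ``accretion_with_melt_episode``: constant accretion except a melt
    interval with the given positive basal rate.
    ``paper_like``: accretion over the first two thirds of the transit and
    mild melting near the end, with per-segment sigma attached (a
    qualitative synthetic stand-in, not a reconstruction of any real shelf).
    """
    n = int(round(scenario.total_time / scenario.dt))
    if n < 1:
        raise ConfigurationError("scenario must span at least one segment")
    dt = scenario.dt
    a = scenario.accretion_rate
    eps = scenario.strain_rate
    times = (np.arange(n) + 0.5) * dt  # segment midpoints in time

    if scenario.name == "constant_accretion":
        ab = np.full(n, -a)
        ezz = np.zeros(n)
        h_form = lambda t: a * t
        T = scenario.total_time
        age_form = lambda depth: T - depth / a
    elif scenario.name == "steady_strain":
        ab = np.full(n, -a)
        ezz = np.full(n, -eps)
        if eps <= 0:
            raise ConfigurationError("steady_strain requires strain_rate > 0")
        h_form = lambda t: (a / eps) * (1.0 - math.exp(-eps * t))
        age_form = None
    elif scenario.name == "accretion_with_melt_episode":
        if scenario.melt_episode is None:
            raise ConfigurationError("melt_episode parameters required")
        t0, t1, melt_rate = scenario.melt_episode
        ab = np.full(n, -a)
        ab[(times >= t0) & (times < t1)] = melt_rate
        ezz = np.zeros(n)
        h_form = None
        age_form = None
    elif scenario.name == "paper_like":
        rng = np.random.default_rng(scenario.seed)
        ab = np.where(
            times < 2.0 / 3.0 * scenario.total_time,
            -a * (1.0 + 0.2 * rng.standard_normal(n)),
            0.3 * a * (1.0 + 0.2 * rng.standard_normal(n)),
        )
        ezz = np.full(n, -abs(eps))
        h_form = None
        age_form = None
    else:
        raise ConfigurationError(f"unknown ice scenario {scenario.name!r}")

    speed = 250.0 / dt  # m/yr so each 250 m segment lasts dt
    segments = tuple(
        FlowlineSegment(
            index=i + 1,
            length=250.0,
            midpoint=(250.0 * (i + 0.5), 0.0),
            speed=speed,
            duration=dt,
            basal_rate=float(ab[i]),
            basal_rate_sigma=scenario.sigma_ab,
            strain_rate=float(ezz[i]),
        )
        for i in range(n)
    )
    return SegmentSeries(
        scenario=scenario,
        segments=segments,
        closed_form_thickness=h_form,
        closed_form_age=age_form,
    )


# ---------------------------------------------------------------------------
# genomes


def make_genome(
    length: int,
    gc: float = 0.5,
    coding_fraction: float = 0.0,
    seed=None,
    name: str = "synthetic_contig",
) -> tuple:
    """Random genome with optional in-frame coding regions free of stops.

    Returns ``(ReferenceGenome, coding_mask)`` where the mask marks coding
    positions.  Coding regions are laid out as alternating genes of ~900 bp
    until the requested fraction is covered; their codons are drawn from the
    base composition conditioned on not being a stop codon (which biases GC
    slightly upward relative to the target in coding regions).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    if not 0 <= coding_fraction <= 1:
        raise ValueError("coding_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    seq = rng.choice(_BASES, size=length, p=p)

    mask = np.zeros(length, dtype=bool)
    if coding_fraction > 0:
        gene_len = 900  # multiple of 3
        target = int(coding_fraction * length)
        covered = 0
        pos = 0
        while covered < target and pos + 3 <= length:
            glen = min(gene_len, length - pos, target - covered)
            glen -= glen % 3
            if glen < 3:
                break
            mask[pos : pos + glen] = True
            covered += glen
            pos += 2 * gene_len  # leave an intergenic gap of one gene length
        # rewrite coding codons, rejecting stops
        starts = _codon_starts(mask)
        for s in starts:
            while True:
                codon = rng.choice(_BASES, size=3, p=p)
                if codon.tobytes().decode() not in STOP_CODONS:
                    break
            seq[s : s + 3] = codon
    genome = reference_from_sequence(seq.tobytes().decode(), name=name)
    return genome, mask


def _codon_starts(mask: np.ndarray) -> np.ndarray:
    """Start index of every full codon inside contiguous True runs of mask."""
    starts = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            starts.extend(range(i, j - 2, 3))
            i = j
        else:
            i += 1
    return np.array(starts, dtype=int)


# ---------------------------------------------------------------------------
# evolution


@dataclass(frozen=True)
class EvolutionTruth:
    """A descendant genome plus the exact planted substitutions."""

    ancestor: ReferenceGenome
    descendant: str
    positions: np.ndarray  # 0-based planted substitution positions
    ref_alleles: tuple
    alt_alleles: tuple
    rate_per_site: float  # r * t actually applied
    kappa: float
    seed: object


def evolve_genome(
    genome: ReferenceGenome,
    rate_per_site: float,
    kappa: float = 2.0,
    omega: float = None,
    coding_mask: np.ndarray = None,
    seed=None,
) -> EvolutionTruth:
    """Plant substitutions at per-site probability ``rate_per_site``.

    Transitions are favored over each transversion by ``kappa`` (a site
    mutates to the transition partner with probability ``kappa/(kappa+2)``).
    Within ``coding_mask`` regions, substitutions creating stop codons are
    never planted.  If ``omega`` is given, candidate coding substitutions
    of the over-represented class (synonymous vs non-synonymous, classified
    against the ancestral codon) are rejected at random until the accepted
    set has non-synonymous fraction ``omega``; note this thins the planted
    count in coding regions below ``Binomial(L, rate_per_site)``.

    Raises
    ------
    ValueError
        If ``rate_per_site >= 0.05`` (multiple-hit/saturation regime the
        simulator does not model).
    """
    if rate_per_site < 0 or rate_per_site >= 0.05:
        raise ValueError("rate_per_site must be in [0, 0.05)")
    if omega is not None and not 0 < omega < 1:
        raise ValueError("omega must be in (0, 1)")
    rng = np.random.default_rng(seed)
    seq = bytearray(genome.sequence, "ascii")
    L = genome.length
    hit = np.nonzero(rng.random(L) < rate_per_site)[0]
    coding = coding_mask if coding_mask is not None else np.zeros(L, dtype=bool)
    starts = {}
    if coding.any():
        for s in _codon_starts(coding):
            for o in range(3):
                starts[s + o] = s

    candidates = []  # (pos, ref, alt, syn_class or None)
    for pos in hit:
        ref = chr(seq[pos])
        if ref not in _BASE_STR:
            continue
        if pos in starts:
            picked = _coding_substitution(seq, pos, starts[pos], kappa, rng)
            if picked is None:
                continue
            alt, is_syn = picked
            candidates.append((int(pos), ref, alt, is_syn))
        else:
            candidates.append((int(pos), ref, _draw_substitution(ref, kappa, rng), None))

    if omega is not None:
        candidates = _enforce_omega(candidates, omega, rng)

    positions, refs, alts = [], [], []
    for pos, ref, alt, _cls in candidates:
        seq[pos] = ord(alt)
        positions.append(pos)
        refs.append(ref)
        alts.append(alt)
    return EvolutionTruth(
        ancestor=genome,
        descendant=seq.decode(),
        positions=np.array(positions, dtype=int),
        ref_alleles=tuple(refs),
        alt_alleles=tuple(alts),
        rate_per_site=rate_per_site,
        kappa=kappa,
        seed=seed,
    )


def _draw_substitution(ref: str, kappa: float, rng) -> str:
    """Alternative base with transition:transversion odds kappa:1:1."""
    ts = _TRANSITION[ref]
    tv = [b for b in _BASE_STR if b != ref and b != ts]
    weights = np.array([kappa, 1.0, 1.0])
    choice = rng.choice(3, p=weights / weights.sum())
    return ts if choice == 0 else tv[choice - 1]


def _coding_substitution(seq, pos, codon_start, kappa, rng):
    """Kappa-weighted non-stop alternative at a coding site, with its class.

    Returns ``(alt_base, is_synonymous)`` or None if every alternative
    creates a stop codon (or the codon itself is unusable).
    """
    codon = bytes(seq[codon_start : codon_start + 3]).decode()
    if any(c not in _BASE_STR for c in codon) or codon in STOP_CODONS:
        return None
    off = pos - codon_start
    aa = CODON_TO_AA[codon]
    pool = []
    for base in _BASE_STR:
        if base == codon[off]:
            continue
        alt_codon = codon[:off] + base + codon[off + 1 :]
        if alt_codon in STOP_CODONS:
            continue
        pool.append((base, CODON_TO_AA[alt_codon] == aa))
    if not pool:
        return None
    ref = codon[off]
    weights = np.array([kappa if b == _TRANSITION[ref] else 1.0 for b, _ in pool])
    return pool[int(rng.choice(len(pool), p=weights / weights.sum()))]


def _enforce_omega(candidates, omega, rng):
    """Subsample coding candidates so non-synonymous make up fraction omega.

    Whichever class is over-represented relative to ``omega`` is randomly
    thinned; non-coding candidates pass through untouched.
    """
    syn_idx = [i for i, c in enumerate(candidates) if c[3] is True]
    non_idx = [i for i, c in enumerate(candidates) if c[3] is False]
    n_s, n_n = len(syn_idx), len(non_idx)
    if n_s + n_n == 0:
        return candidates
    keep = set(range(len(candidates)))
    target_n = omega / (1.0 - omega) * n_s
    if n_n > target_n:
        drop = rng.choice(non_idx, size=n_n - int(round(target_n)), replace=False)
        keep -= set(int(i) for i in drop)
    else:
        target_s = (1.0 - omega) / omega * n_n
        if n_s > target_s:
            drop = rng.choice(syn_idx, size=n_s - int(round(target_s)), replace=False)
            keep -= set(int(i) for i in drop)
    return [c for i, c in enumerate(candidates) if i in keep]


# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class SimulatedRead:
    """One read with its exact origin and planted error positions."""

    name: str
    sequence: str  # read-strand sequence (as written to FASTQ)
    start: int  # 0-based leftmost reference position
    reverse: bool
    errors: tuple  # error offsets within the forward-strand fragment


@dataclass(frozen=True)
class ReadSet:
    reads: tuple
    reference_name: str
    reference_length: int
    read_length: int
    coverage: float
    error_rate: float
    seed: object


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_reads(
    genome: str,
    coverage: float,
    read_len: int = 150,
    paired: bool = False,
    err_rate: float = 0.0,
    seed=None,
    insert_size: int = 400,
    name: str = "synthetic_contig",
) -> ReadSet:
    """Uniform-coverage reads with per-base substitution errors.

    ``genome`` is the (descendant) sequence the reads are drawn from.
    Fragments start uniformly; for ``paired`` sets, mates are taken from
    the opposite ends of an ``insert_size`` fragment, the second mate on
    the reverse strand.  Every read is an exact substring of the genome
    apart from its planted errors.  Deterministic under ``seed``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    L = len(genome)
    if read_len > L:
        raise ValueError("read_len exceeds genome length")
    rng = np.random.default_rng(seed)
    n_reads = max(1, int(round(coverage * L / read_len)))
    if paired:
        n_reads += n_reads % 2  # whole pairs

    reads = []
    if paired:
        span = max(insert_size, read_len)
        n_pairs = n_reads // 2
        starts = rng.integers(0, max(L - span, 1), size=n_pairs)
        for k, frag_start in enumerate(starts):
            r1, e1 = _make_read(genome, int(frag_start), read_len, err_rate, rng)
            m_start = int(frag_start) + span - read_len
            r2raw, e2 = _make_read(genome, m_start, read_len, err_rate, rng)
            reads.append(
                SimulatedRead(f"read{k}/1", r1, int(frag_start), False, e1)
            )
            reads.append(SimulatedRead(f"read{k}/2", _revcomp(r2raw), m_start, True, e2))
    else:
        starts = rng.integers(0, L - read_len + 1, size=n_reads)
        flip = rng.random(n_reads) < 0.5
        for k, (s, rev) in enumerate(zip(starts, flip)):
            raw, errs = _make_read(genome, int(s), read_len, err_rate, rng)
            seqout = _revcomp(raw) if rev else raw
            reads.append(SimulatedRead(f"read{k}", seqout, int(s), bool(rev), errs))
    return ReadSet(
        reads=tuple(reads),
        reference_name=name,
        reference_length=L,
        read_length=read_len,
        coverage=coverage,
        error_rate=err_rate,
        seed=seed,
    )


def _make_read(genome: str, start: int, read_len: int, err_rate: float, rng):
    """Forward-strand substring with planted substitution errors."""
    frag = list(genome[start : start + read_len])
    errs = []
    if err_rate > 0:
        where = np.nonzero(rng.random(read_len) < err_rate)[0]
        for i in where:
            orig = frag[i]
            if orig not in _BASE_STR:
                continue
            others = [b for b in _BASE_STR if b != orig]
            frag[i] = others[int(rng.integers(3))]
            errs.append(int(i))
    return "".join(frag), tuple(errs)


def write_fastq(readset: ReadSet, path) -> None:
    """Write reads as FASTQ with uniform quality 'I' (Q40)."""
    with open(path, "w") as fh:
        for r in readset.reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_truth_sam(readset: ReadSet, path) -> None:
    """Write the exact truth alignment: all-match CIGAR at the true start.

    Reverse-strand reads get FLAG 16 and their SEQ stored forward-strand
    (reverse complement of the FASTQ sequence), per SAM convention.
    """
    qual = "I" * readset.read_length
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(
            f"@SQ\tSN:{readset.reference_name}\tLN:{readset.reference_length}\n"
        )
        fh.write(f"@PG\tID:iceclock-simulate\tPN:iceclock-simulate\n")
        for r in readset.reads:
            flag = 16 if r.reverse else 0
            seq = _revcomp(r.sequence) if r.reverse else r.sequence
            fh.write(
                f"{r.name}\t{flag}\t{readset.reference_name}\t{r.start + 1}\t60\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t{qual}\n"
            )


def write_fasta(sequence: str, path, name: str = "synthetic_contig", width: int = 80):
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")
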