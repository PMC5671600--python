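"""Synthetic communities with known ground truth.

Population genomes are realized from order-2 Markov chains (16 conditioning
dinucleotides x 4 next-base probabilities). Trimer-frequency classification is
exactly the statistic these chains control: the expected trimer profile is
pi(ab) * P(c|ab) with pi the stationary dinucleotide distribution, so the
separability of a community is tunable through its transition matrices. A
helper constructs K populations with a target minimum pairwise Jensen-Shannon
divergence between stationary trimer profiles by scaling random perturbations
of a shared base matrix.

Partial references ("SAG-like" assemblies, 40-78% complete in the real data
this emulates) are simulated as disjoint sub-intervals of a genome; reads are
drawn with skewed abundances, truncated-normal lengths (pyrosequencing-like:
mean 400, sd 100, min 50) and i.i.d. substitution errors. Populations listed
in ``decoy_labels`` contribute reads but no training material, emulating taxa
present in the environment but absent from the anchor set — the false-positive
side of threshold calibration.

Fixed (spec, seed) gives bit-identical output across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import SeqRecord
from .evaluation import js_divergence

BASES = "ACGT"
GroundTruth = dict  # read_id -> true population label


def _check_transition(transition: np.ndarray) -> np.ndarray:
    t = np.asarray(transition, dtype=float)
    if t.shape != (16, 4):
        raise ValueError("transition must have shape (16, 4)")
    if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-12):
        raise ValueError("each transition row must be a probability vector (sum 1)")
    return t


@dataclass(frozen=True)
class PopulationSpec:
    """One population: a label, a genome length, and its order-2 Markov model."""

    label: str
    genome_length: int
    transition: np.ndarray  # (16, 4): row = dinucleotide (4*a+b), col = next base
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "transition", _check_transition(self.transition))
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10,000")


@dataclass(frozen=True)
class CommunitySpec:
    populations: tuple[PopulationSpec, ...]
    abundances: tuple[float, ...]
    n_reads: int
    read_length: tuple[float, float] = (400.0, 100.0)  # truncated normal, min 50
    substitution_rate: float = 0.01
    decoy_labels: frozenset[str] = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "abundances", tuple(float(a) for a in self.abundances))
        object.__setattr__(self, "decoy_labels", frozenset(self.decoy_labels))
        if len(self.abundances) != len(self.populations):
            raise ValueError("one abundance per population required")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        if not 0.0 <= self.substitution_rate <= 0.2:
            raise ValueError("substitution_rate must be in [0, 0.2]")
        labels = {p.label for p in self.populations}
        if not self.decoy_labels <= labels:
            raise ValueError("decoy_labels must be a subset of population labels")


# ---------------------------------------------------------------------------
# Markov-chain machinery
# ---------------------------------------------------------------------------

def dinucleotide_chain(transition: np.ndarray) -> np.ndarray:
    """The 16-state chain over dinucleotides: (a,b) -> (b,c) w.p. P(c|ab)."""
    t = _check_transition(transition)
    T = np.zeros((16, 16))
    for s in range(16):
        b = s & 3
        for c in range(4):
            T[s, 4 * b + c] = t[s, c]
    return T


def stationary_dinucleotides(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution over the 16 dinucleotide states (power iteration)."""
    T = dinucleotide_chain(transition)
    pi = np.full(16, 1 / 16)
    for _ in range(10_000):
        new = pi @ T
        if np.abs(new - pi).sum() < 1e-14:
            pi = new
            break
        pi = new
    return pi / pi.sum()


def stationary_trimer_profile(transition: np.ndarray) -> np.ndarray:
    """Expected trimer frequencies under the chain: p(abc) = pi(ab) P(c|ab)."""
    t = _check_transition(transition)
    pi = stationary_dinucleotides(t)
    return (pi[:, None] * t).ravel()


def _min_pairwise_jsd(transitions: Sequence[np.ndarray]) -> float:
    profiles = [stationary_trimer_profile(t) for t in transitions]
    best = np.inf
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            best = min(best, js_divergence(profiles[i], profiles[j]))
    return best


def design_populations(
    n_populations: int,
    target_jsd: float,
    seed: int,
    base_transition: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Transition matrices whose stationary trimer profiles are separated by at
    least ``target_jsd`` bits pairwise (within 2% of the target at the minimum).

    Each population's matrix is the shared base matrix with a population-
    specific random log-scale perturbation, scaled by a common factor found by
    bisection on the minimum pairwise JSD. Independent perturbation directions
    are near-orthogonal in profile space, so every pair — including any decoy —
    is separated by about the same amount.
    """
    if n_populations < 2:
        raise ValueError("need at least 2 populations")
    if not 0 < target_jsd < 1:
        raise ValueError("target_jsd must be in (0, 1) bits")
    rng = np.random.default_rng(seed)
    if base_transition is None:
        base = rng.dirichlet([5.0, 5.0, 5.0, 5.0], size=16)
    else:
        base = _check_transition(base_transition)

    for _attempt in range(20):
        dirs = rng.normal(0.0, 1.0, size=(n_populations, 16, 4))
        dirs -= dirs.mean(axis=2, keepdims=True)

        def build(alpha: float) -> list[np.ndarray]:
            mats = []
            for k in range(n_populations):
                m = base * np.exp(alpha * dirs[k])
                mats.append(m / m.sum(axis=1, keepdims=True))
            return mats

        lo, hi = 0.0, 0.05
        reachable = True
        while _min_pairwise_jsd(build(hi)) < target_jsd:
            hi *= 2.0
            if hi > 50.0:
                # perturbations saturate below the target; redraw directions
                reachable = False
                break
        if not reachable:
            continue
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _min_pairwise_jsd(build(mid)) < target_jsd:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-6 * hi:
                break
        return build(hi)  # upper end: min pairwise JSD >= target
    raise RuntimeError("cannot reach target JSD with these perturbations")


# ---------------------------------------------------------------------------
# Genome / SAG / read simulation
# ---------------------------------------------------------------------------

def generate_genome(spec: PopulationSpec) -> SeqRecord:
    """Realize one genome from the population's Markov chain.

    The first dinucleotide is drawn from the chain's stationary distribution;
    every later base from the conditional row. Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length
    pi = stationary_dinucleotides(spec.transition)
    state = int(rng.choice(16, p=pi))
    out = bytearray(L)
    out[0] = ord(BASES[state >> 2])
    out[1] = ord(BASES[state & 3])
    cums = [tuple(row) for row in np.cumsum(spec.transition, axis=1)]
    u = rng.random(L - 2)
    base_ord = tuple(ord(b) for b in BASES)
    for i in range(L - 2):
        r0, r1, r2, _ = cums[state]
        ui = u[i]
        c = 0 if ui < r0 else 1 if ui < r1 else 2 if ui < r2 else 3
        out[i + 2] = base_ord[c]
        state = ((state & 3) << 2) | c
    return SeqRecord(id=spec.label, seq=out.decode("ascii"))


def simulate_sag(
    genome: SeqRecord, completeness: float, n_contigs: int, seed: int
) -> list[SeqRecord]:
    """Cut a partial, fragmented reference out of a genome.

    Returns ``n_contigs`` non-overlapping contigs named ``<genome>.c1..``,
    totaling ``round(completeness * len(genome))`` bases; each contig's
    0-based half-open source interval is recorded in its description.
    """
    if not 0.0 < completeness <= 1.0:
        raise ValueError("completeness must be in (0, 1]")
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    L = len(genome.seq)
    total_keep = round(completeness * L)
    if total_keep < n_contigs * 500:
        raise ValueError(
            f"completeness x genome_length = {total_keep} bases cannot support "
            f"{n_contigs} contigs of >= 500 bp"
        )
    rng = np.random.default_rng(seed)

    def _split(total: int, parts: int, minimum: int) -> np.ndarray:
        extra = total - parts * minimum
        if parts == 1:
            return np.array([total])
        w = rng.dirichlet(np.ones(parts))
        sizes = np.floor(w * extra).astype(int) + minimum
        sizes[0] += total - sizes.sum()
        return sizes

    keep = _split(total_keep, n_contigs, 500)
    gaps = _split(L - total_keep, n_contigs + 1, 0)
    contigs = []
    pos = 0
    for i in range(n_contigs):
        pos += int(gaps[i])
        start, end = pos, pos + int(keep[i])
        contigs.append(
            SeqRecord(
                id=f"{genome.id}.c{i + 1}",
                seq=genome.seq[start:end],
                description=f"{start}:{end}",
            )
        )
        pos = end
    return contigs


@dataclass(frozen=True)
class BenchmarkCommunity:
    """One realized benchmark scenario: genomes, SAG-like anchors, reads, truth."""

    community: CommunitySpec
    genomes: dict  # label -> SeqRecord
    sags: dict     # label -> list[SeqRecord]; decoys have no entry
    reads: list
    truth: GroundTruth

    @property
    def anchor_labels(self) -> list[str]:
        return sorted(self.sags)


def benchmark_community(
    seed: int,
    n_populations: int = 5,
    n_decoys: int = 1,
    target_jsd: float = 0.05,
    genome_length: int = 1_000_000,
    completeness: float = 0.6,
    n_contigs: int = 8,
    n_reads: int = 20_000,
    read_length: tuple[float, float] = (400.0, 100.0),
    substitution_rate: float = 0.01,
    abundances: Sequence[float] | None = None,
) -> BenchmarkCommunity:
    """The default ground-truth scenario the pipeline is validated on.

    Five genome-scale populations (1 Mb, matching the size range of the real
    anchor genomes) separated by at least ``target_jsd`` bits between
    stationary trimer profiles; partial SAG-like references (60% complete, 8
    contigs) for all but the last ``n_decoys`` populations; 20,000 reads with
    skewed abundances, pyrosequencing-like lengths and 1% substitution noise.
    Fully determined by ``seed``.
    """
    transitions = design_populations(n_populations, target_jsd, seed=seed)
    labels = [f"pop{chr(ord('A') + i)}" for i in range(n_populations)]
    pops = tuple(
        PopulationSpec(
            label=lab, genome_length=genome_length, transition=t, seed=seed + 10 + i
        )
        for i, (lab, t) in enumerate(zip(labels, transitions))
    )
    decoys = frozenset(labels[-n_decoys:]) if n_decoys else frozenset()
    genomes = {p.label: generate_genome(p) for p in pops}
    sags = {
        p.label: simulate_sag(
            genomes[p.label], completeness, n_contigs, seed=seed + 100 + i
        )
        for i, p in enumerate(pops)
        if p.label not in decoys
    }
    if abundances is None:
        base = np.array([0.3, 0.25, 0.2, 0.15, 0.1])
        if n_populations != 5:
            base = np.linspace(2.0, 1.0, n_populations)
        abundances = tuple(base / base.sum())
    community = CommunitySpec(
        populations=pops,
        abundances=tuple(abundances),
        n_reads=n_reads,
        read_length=read_length,
        substitution_rate=substitution_rate,
        decoy_labels=decoys,
        seed=seed,
    )
    reads, truth = simulate_reads(community, genomes)
    return BenchmarkCommunity(
        community=community, genomes=genomes, sags=sags, reads=reads, truth=truth
    )


_B2I = {b: i for i, b in enumerate(BASES)}


def simulate_reads(
    community: CommunitySpec, genomes: Mapping[str, SeqRecord]
) -> tuple[list[SeqRecord], GroundTruth]:
    """Draw reads from the community with complete ground truth.

    Each read's population follows the abundance vector, its start is uniform,
    its strand uniform, its length truncated-normal (resampled below the
    minimum of 50), and substitutions are i.i.d. at ``substitution_rate``
    (each substituted base becomes one of the other three, uniformly).
    """
    for pop in community.populations:
        if pop.label not in genomes:
            raise ValueError(f"no genome provided for population {pop.label!r}")
    rng = np.random.default_rng(community.seed)
    n = community.n_reads
    if n == 0:
        return [], {}
    labels = [p.label for p in community.populations]
    codes = {}
    for lab in labels:
        g = genomes[lab].seq
        codes[lab] = np.frombuffer(g.encode("ascii"), dtype=np.uint8)

    mean, sd = community.read_length
    pop_idx = rng.choice(len(labels), size=n, p=np.array(community.abundances))
    lengths = rng.normal(mean, sd, size=n)
    while np.any(lengths < 50):
        bad = lengths < 50
        lengths[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    lengths = np.round(lengths).astype(int)

    comp_map = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp_map[a] = b

    width = max(6, len(str(n - 1)))
    reads: list[SeqRecord] = []
    truth: GroundTruth = {}
    rate = community.substitution_rate
    shift_map = np.array([_B2I.get(chr(c), 4) for c in range(256)], dtype=np.uint8)
    for i in range(n):
        lab = labels[pop_idx[i]]
        g = codes[lab]
        rl = int(lengths[i])
        if rl > g.size:
            raise ValueError(
                f"read of length {rl} longer than genome of {lab!r} ({g.size} bp)"
            )
        start = int(rng.integers(0, g.size - rl + 1))
        frag = g[start : start + rl].copy()
        minus = bool(rng.random() < 0.5)
        if minus:
            frag = comp_map[frag][::-1].copy()
        if rate > 0:
            mask = rng.random(rl) < rate
            k = int(mask.sum())
            if k:
                old = shift_map[frag[mask]]
                subst = np.where(old < 4)[0]
                shifts = rng.integers(1, 4, size=k).astype(np.uint8)
                newb = (old + shifts) % 4
                vals = frag[mask]
                vals[subst] = np.frombuffer(BASES.encode(), dtype=np.uint8)[
                    newb[subst]
                ]
                frag[mask] = vals
        rid = f"read{i:0{width}d}"
        reads.append(SeqRecord(id=rid, seq=frag.tobytes().decode("ascii")))
        truth[rid] = lab
    return reads, truth
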