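"""Seeded generators for synthetic breeding cohorts and the Ms-locus alleles.

The cohort generator emulates the statistical structure of a radicchio
breeding core collection: a handful of strongly diverged full-sib
populations genotyped at a few thousand complete-call biallelic SNPs, with
high within-population similarity and homozygosity, one admixed population,
sporadic missing calls, and a diploid male-sterility locus whose sterile
allele carries a 4-nt AATT insertion.

Divergence follows the Balding-Nichols model: population founder allele
frequencies are Beta-distributed around an ancestral frequency with
variance theta * p * (1 - p), so ``fst`` is the divergence parameter.
Inbreeding is produced mechanistically by repeated full-sib mating with
Mendelian gamete draws. Every generator is deterministic given its seed;
each operation derives its own RNG stream from the master seed by stable
labelled splitting, so adding operations never perturbs existing outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype import MISSING, GenotypeDataset, Locus


def _rng(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible stream for one labelled operation."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# configuration and truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdmixtureSpec:
    """Target population rebuilt with gametes drawn from two sources."""

    target: str
    sources: tuple[str, str]
    proportion: float = 0.5  # probability a gamete comes from sources[0]

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("admixture proportion must lie in [0,1]")


@dataclass(frozen=True)
class CohortConfig:
    """Defaults emulate the study cohort: four full-sib populations of
    15/17/37/25 plants, ~9300 SNP loci thinned to ~3000 complete-call loci
    by a 1.2% per-call missing rate, strong divergence (theta = 0.5),
    three generations of sib mating, and one population admixed 50:50
    with its neighbour."""

    n_loci: int = 9351
    pop_sizes: tuple[int, ...] = (15, 17, 37, 25)
    fst: float = 0.5
    sib_generations: int = 3
    admixture: AdmixtureSpec | None = AdmixtureSpec("Pop1", ("Pop1", "Pop2"), 0.5)
    missing_rate: float = 0.012
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if any(n < 1 for n in self.pop_sizes):
            raise ValueError("population sizes must be >= 1")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie strictly inside (0,1)")
        if self.sib_generations < 0:
            raise ValueError("sib_generations must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0,1)")


@dataclass
class TruthRecord:
    """Generator-side truth, sufficient to compute expected statistics."""

    ancestral_freqs: np.ndarray | None = None
    founder_freqs: dict[str, np.ndarray] = field(default_factory=dict)
    pedigree: list[dict] = field(default_factory=list)
    missing_mask: np.ndarray | None = None
    ms_genotypes: dict[str, str] = field(default_factory=dict)
    config: CohortConfig | None = None


# ---------------------------------------------------------------------------
# allele-frequency and genotype simulation
# ---------------------------------------------------------------------------


def simulate_ancestral_freqs(n_loci: int, seed: int) -> np.ndarray:
    """Ancestral allele-A frequencies, Uniform(0.1, 0.9)."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    return _rng(seed, "ancestral").uniform(0.1, 0.9, n_loci)


def _counts_to_codes(a_copies: np.ndarray) -> np.ndarray:
    """Allele-A copy number (0/1/2) -> genotype code (1/2/0)."""
    codes = np.full(a_copies.shape, 2, dtype=np.int8)
    codes[a_copies == 2] = 0
    codes[a_copies == 0] = 1
    return codes


def _codes_to_counts(codes: np.ndarray) -> np.ndarray:
    out = np.full(codes.shape, -1, dtype=np.int8)
    out[codes == 0] = 2
    out[codes == 1] = 0
    out[codes == 2] = 1
    return out


def _make_loci(n_loci: int) -> list[Locus]:
    width = len(str(n_loci))
    return [Locus(f"locus_{i + 1:0{width}d}") for i in range(n_loci)]


def simulate_populations(
    ancestral_freqs: np.ndarray,
    fst: float,
    pop_sizes: Sequence[int],
    seed: int,
    pop_names: Sequence[str] | None = None,
) -> tuple[GenotypeDataset, TruthRecord]:
    """Draw diverged founder populations under the Balding-Nichols model.

    Per population and locus the founder frequency is
    Beta(p(1-theta)/theta, (1-p)(1-theta)/theta) with theta = *fst*;
    founder genotypes are then drawn in Hardy-Weinberg proportions.
    Ancestral frequencies of exactly 0 or 1 stay fixed.
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must lie strictly inside (0,1)")
    p = np.asarray(ancestral_freqs, dtype=float)
    n_loci = p.size
    if pop_names is None:
        pop_names = [f"Pop{i + 1}" for i in range(len(pop_sizes))]
    loci = _make_loci(n_loci)
    truth = TruthRecord(ancestral_freqs=p.copy())
    samples: list[str] = []
    pops: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    scale = (1.0 - fst) / fst
    for name, size in zip(pop_names, pop_sizes):
        rng = _rng(seed, f"founders:{name}")
        interior = (p > 0) & (p < 1)
        freqs = p.copy()
        if interior.any():
            freqs[interior] = rng.beta(p[interior] * scale, (1 - p[interior]) * scale)
        truth.founder_freqs[name] = freqs
        a_copies = rng.binomial(2, freqs, size=(size, n_loci)).astype(np.int8)
        blocks.append(_counts_to_codes(a_copies))
        ids = [f"{name}-{i + 1:02d}" for i in range(size)]
        samples.extend(ids)
        pops.update({s: name for s in ids})
    calls = np.vstack(blocks)
    return GenotypeDataset(samples, pops, loci, calls), truth


def _gametes(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One haploid gamete (allele-A copies 0/1 per locus) per parent row."""
    het = counts == 1
    g = (counts // 2).astype(np.int8)  # hom AA -> 1, hom BB -> 0
    g[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return g


def sib_mate(
    ds: GenotypeDataset,
    generations: int,
    seed: int,
    family_size: int | None = None,
    selfing: bool = False,
) -> GenotypeDataset:
    """Advance each population by repeated full-sib mating (or selfing).

    Each generation one parental pair (one parent when *selfing*) is drawn
    per population and produces the whole next generation by independent
    Mendelian gamete draws per locus; sample ids and population sizes are
    preserved unless *family_size* overrides the sizes.
    """
    if generations == 0:
        return ds
    new_blocks: list[np.ndarray] = []
    samples: list[str] = []
    pops: dict[str, str] = {}
    for name in ds.population_labels():
        rng = _rng(seed, f"sibmate:{name}")
        idx = ds.population_indices(name)
        counts = _codes_to_counts(ds.calls[idx])
        size = family_size if family_size is not None else idx.size
        if not selfing and size < 2:
            raise ValueError("family_size must be >= 2 in the full-sib regime")
        if not selfing and counts.shape[0] < 2:
            raise ValueError(f"population {name!r} needs >= 2 individuals for sib mating")
        for _ in range(generations):
            if selfing:
                parent = counts[rng.integers(counts.shape[0])]
                mother = father = parent
            else:
                i, j = rng.choice(counts.shape[0], size=2, replace=False)
                mother, father = counts[i], counts[j]
            mom = np.tile(mother, (size, 1))
            dad = np.tile(father, (size, 1))
            counts = _gametes(mom, rng) + _gametes(dad, rng)
        new_blocks.append(_counts_to_codes(counts))
        ids = [f"{name}-{i + 1:02d}" for i in range(size)]
        samples.extend(ids)
        pops.update({s: name for s in ids})
    return GenotypeDataset(samples, pops, list(ds.loci), np.vstack(new_blocks))


def simulate_admixture(
    ds: GenotypeDataset,
    spec: AdmixtureSpec,
    seed: int,
) -> GenotypeDataset:
    """Rebuild the target population with gametes drawn from two sources.

    Each individual of the target draws each of its two gametes from the
    empirical allele frequencies of source A with probability
    ``proportion`` and from source B otherwise — a 50:50 proportion gives
    F1-like mixed ancestry.
    """
    from .popgen import allele_frequencies

    rng = _rng(seed, f"admixture:{spec.target}")
    freq_a = allele_frequencies(ds, spec.sources[0])
    freq_b = allele_frequencies(ds, spec.sources[1])
    idx = ds.population_indices(spec.target)
    n, n_loci = idx.size, ds.n_loci
    counts = np.zeros((n, n_loci), dtype=np.int8)
    for gamete in range(2):
        from_a = rng.random((n, n_loci)) < spec.proportion
        p = np.where(from_a, freq_a[None, :], freq_b[None, :])
        counts += (rng.random((n, n_loci)) < p).astype(np.int8)
    calls = ds.calls.copy()
    calls[idx] = _counts_to_codes(counts)
    return GenotypeDataset(list(ds.samples), dict(ds.populations), list(ds.loci), calls)


def inject_missing(
    ds: GenotypeDataset, rate: float, seed: int
) -> tuple[GenotypeDataset, np.ndarray]:
    """Set each call MISSING independently with probability *rate*."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0,1)")
    rng = _rng(seed, "missing")
    mask = rng.random(ds.calls.shape) < rate
    calls = ds.calls.copy()
    calls[mask] = MISSING
    out = GenotypeDataset(list(ds.samples), dict(ds.populations), list(ds.loci), calls)
    return out, mask


def synth_cohort(config: CohortConfig) -> tuple[GenotypeDataset, TruthRecord]:
    """Compose the full synthetic cohort from the configured stages.

    Order: diverged founders -> admixture of the target population ->
    sib-mating -> missing-call injection. Deterministic given
    ``config.seed``.
    """
    p = simulate_ancestral_freqs(config.n_loci, config.seed)
    ds, truth = simulate_populations(p, config.fst, config.pop_sizes, config.seed)
    truth.config = config
    if config.admixture is not None:
        ds = simulate_admixture(ds, config.admixture, config.seed)
    if config.sib_generations > 0:
        ds = sib_mate(ds, config.sib_generations, config.seed)
        truth.pedigree.append(
            {"kind": "full_sib", "generations": config.sib_generations}
        )
    if config.missing_rate > 0:
        ds, mask = inject_missing(ds, config.missing_rate, config.seed)
        truth.missing_mask = mask
    return ds, truth


# ---------------------------------------------------------------------------
# Ms-locus allele construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Myb80Locus:
    """Synthetic fertile/sterile allele pair for the CAPS assay.

    ``fertile`` and ``sterile`` are full templates (amplicon plus genomic
    flanks). The fertile amplicon is 298 bp with no Tru1I site; the sterile
    allele carries the AATT insertion placed so its 302-bp amplicon digests
    into 230 + 72 bp fragments.
    """

    fertile: str
    sterile: str
    fwd: "object"
    rev: "object"

    def alleles_for(self, genotype: str) -> tuple[str, str]:
        pair = {
            "MsMs": (self.fertile, self.fertile),
            "Msms": (self.fertile, self.sterile),
            "msms": (self.sterile, self.sterile),
        }
        try:
            return pair[genotype]
        except KeyError:
            raise ValueError(f"unknown Ms-locus genotype {genotype!r}") from None


def synth_myb80_locus(seed: int = 0, flank: int = 60) -> Myb80Locus:
    """Construct a synthetic Ms-locus allele pair, deterministic given seed.

    The fertile amplicon is forward primer + filler + reverse-complemented
    reverse primer, 298 bp total, rejected and redrawn until it contains no
    recognition site and the primers occur nowhere else. The sterile allele
    inserts AATT immediately after a TT dinucleotide fixed at amplicon
    positions 229-230 (1-based), creating exactly one T^TAA cut whose 5'
    fragment is 230 bp.
    """
    from Bio.Seq import Seq

    from .caps import CIMYB80_FOR, CIMYB80_REV, TRU1I, digest, in_silico_pcr

    fwd, rev = CIMYB80_FOR, CIMYB80_REV
    rc_rev = str(Seq(rev.sequence).reverse_complement())
    amp_len = 298
    filler_len = amp_len - len(fwd.sequence) - len(rc_rev)
    rng = _rng(seed, "myb80")
    bases = np.array(list("ACGT"))
    for _ in range(200):
        filler = "".join(rng.choice(bases, filler_len))
        amplicon = fwd.sequence + filler + rc_rev
        # force a TT dinucleotide at 0-based 229-230 (so the T^TAA cut falls
        # after base 230) and a non-A follower to keep the fertile allele uncut
        amplicon = amplicon[:229] + "TT" + amplicon[231:]
        if amplicon[231] == "A":
            amplicon = amplicon[:231] + "G" + amplicon[232:]
        upstream = "".join(rng.choice(bases, flank))
        downstream = "".join(rng.choice(bases, flank))
        fertile = upstream + amplicon + downstream
        sterile_amplicon = amplicon[:231] + "AATT" + amplicon[231:]
        sterile = upstream + sterile_amplicon + downstream
        if TRU1I.motif in amplicon:
            continue
        if digest(sterile_amplicon, TRU1I) != (230, 72):
            continue
        amps_f = in_silico_pcr(fertile, fwd, rev, template_id="fertile")
        amps_s = in_silico_pcr(sterile, fwd, rev, template_id="sterile")
        if [a.length for a in amps_f] != [298] or [a.length for a in amps_s] != [302]:
            continue
        return Myb80Locus(fertile=fertile, sterile=sterile, fwd=fwd, rev=rev)
    raise RuntimeError("failed to construct a valid Ms-locus fixture")


def simulate_mendelian_offspring(
    ds: GenotypeDataset,
    parent1: str,
    parent2: str,
    n_offspring: int,
    seed: int,
) -> np.ndarray:
    """Heterozygote counts per locus among simulated Mendelian offspring.

    Each offspring receives one independent gamete from each parent at
    every locus; the return value is the per-locus count of heterozygous
    offspring, suitable as a Monte-Carlo check of the analytic progeny
    heterozygosity prediction.
    """
    rng = _rng(seed, f"offspring:{parent1}x{parent2}")
    c1 = _codes_to_counts(ds.calls[ds.sample_index(parent1)])
    c2 = _codes_to_counts(ds.calls[ds.sample_index(parent2)])
    if (c1 < 0).any() or (c2 < 0).any():
        raise ValueError("parents have missing calls")
    # Per locus, draw how many offspring receive an A gamete from each
    # parent (binomial on the parent's gamete-A probability 0/0.5/1), then
    # how many received A from both (hypergeometric pairing of the two
    # gamete pools). Heterozygotes received A from exactly one parent.
    # This aggregation is distributionally exact for independent offspring.
    n = n_offspring
    a1 = rng.binomial(n, c1 / 2.0)
    a2 = rng.binomial(n, c2 / 2.0)
    both = rng.hypergeometric(a1, n - a1, a2)
    het = a1 + a2 - 2 * both
    return het
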