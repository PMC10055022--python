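"""In-silico CAPS assay for the nuclear male-sterility locus of chicory.

A Cleaved Amplified Polymorphic Sequence (CAPS) assay distinguishes the
wild-type (*Ms*, fertile) and insertion-bearing (*ms*, sterile) alleles of
the *myb80-like* gene: PCR around the insertion site, digestion with Tru1I
(canonical recognition site 5'-T^TAA-3'), and genotype calling from the gel
band pattern. The 4-nt AATT insertion creates the restriction site, so the
sterile-allele amplicon is cut (~230 + ~70 bp bands) while the fertile
amplicon stays intact (~300 bp). Sterility is recessive with full
penetrance: only *msms* plants are sterile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str  # 5' -> 3'

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"primer {self.name!r}: empty sequence")
        if set(self.sequence) - _ACGT:
            raise ValueError(
                f"primer {self.name!r}: ambiguous or invalid bases in {self.sequence!r}"
            )


#: The published primer pair flanking the myb80-like insertion site.
CIMYB80_FOR = Primer("CiMyb80_for", "ACTGCGGTTGCTGGTCA")
CIMYB80_REV = Primer("CiMyb80_rev", "CCCTGCTCATGCTCCTG")


@dataclass(frozen=True)
class Amplicon:
    """A virtual PCR product; coordinates are 1-based inclusive, plus strand."""

    template_id: str
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("amplicon coordinates inconsistent with sequence length")


@dataclass(frozen=True)
class RestrictionSite:
    """Recognition motif and cut offset, e.g. T^TAA -> motif TTAA, offset 1."""

    motif: str = "TTAA"
    offset: int = 1

    def __post_init__(self) -> None:
        if not self.motif or set(self.motif) - _ACGT:
            raise ValueError(f"invalid recognition motif {self.motif!r}")
        if not 0 <= self.offset <= len(self.motif):
            raise ValueError("cut offset must lie within the motif")


TRU1I = RestrictionSite("TTAA", 1)


def _find_matches(template: str, probe: str, max_mismatch: int) -> list[int]:
    """0-based start positions where *probe* matches, 3'-end always exact."""
    hits = []
    if max_mismatch == 0:
        start = template.find(probe)
        while start != -1:
            hits.append(start)
            start = template.find(probe, start + 1)
        return hits
    m = len(probe)
    for start in range(len(template) - m + 1):
        window = template[start : start + m]
        if window[-1] != probe[-1]:  # 3'-terminal mismatch disqualifies
            continue
        mismatches = sum(a != b for a, b in zip(window, probe))
        if mismatches <= max_mismatch:
            hits.append(start)
    return hits


def in_silico_pcr(
    template: str,
    fwd: Primer = CIMYB80_FOR,
    rev: Primer = CIMYB80_REV,
    max_mismatch: int = 0,
    max_length: int = 5000,
    template_id: str = "template",
) -> list[Amplicon]:
    """Virtual PCR: every productive forward/reverse primer pairing.

    The forward primer anneals on the plus strand; the reverse primer is
    matched as its reverse complement downstream. Amplicons longer than
    *max_length* are discarded. An empty list (no productive pair) is a
    valid result, distinct from an error.
    """
    if not template:
        raise ValueError("empty template sequence")
    template = template.upper()
    rc_rev = str(Seq(rev.sequence).reverse_complement())
    # 3' end of the annealed reverse primer is the *first* base of rc_rev
    fwd_hits = _find_matches(template, fwd.sequence, max_mismatch)
    rev_hits = _find_matches(template, rc_rev, max_mismatch)
    amplicons = []
    for f in fwd_hits:
        for r in rev_hits:
            end = r + len(rc_rev)  # exclusive
            if end <= f:
                continue
            length = end - f
            if length < len(fwd.sequence) + len(rc_rev) or length > max_length:
                continue
            amplicons.append(
                Amplicon(template_id, f + 1, end, template[f:end])
            )
    return amplicons


def digest(seq: str, site: RestrictionSite = TRU1I) -> tuple[int, ...]:
    """Fragment lengths after cutting at every motif occurrence, 5' to 3'.

    Overlapping occurrences each cut once at their own offset; fragment
    lengths always sum to the input length.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    cuts = set()
    start = seq.find(site.motif)
    while start != -1:
        pos = start + site.offset
        if 0 < pos < len(seq):
            cuts.add(pos)
        start = seq.find(site.motif, start + 1)
    bounds = [0, *sorted(cuts), len(seq)]
    return tuple(b - a for a, b in zip(bounds, bounds[1:]))


def diploid_band_pattern(
    allele1: str, allele2: str, site: RestrictionSite = TRU1I
) -> tuple[int, ...]:
    """Merged gel bands of both alleles (equal fragment sizes collapse)."""
    bands = set(digest(allele1, site)) | set(digest(allele2, site))
    return tuple(sorted(bands, reverse=True))


#: Reference band sizes of the assay (bp): uncut amplicon and the two
#: restriction fragments of the insertion-bearing allele.
REFERENCE_BANDS = {"uncut": 300, "cut_long": 230, "cut_short": 70}


@dataclass(frozen=True)
class MsGenotypeCall:
    bands: tuple[int, ...]
    genotype: str | None  # 'MsMs' | 'Msms' | 'msms' | None (no-call)
    phenotype: str | None  # 'fertile' | 'sterile' | None

    @property
    def is_no_call(self) -> bool:
        return self.genotype is None


def call_ms_genotype(
    bands: Iterable[int],
    tolerance_bp: int = 15,
    low_band_dropout: bool = False,
) -> MsGenotypeCall:
    """Classify a band pattern into an Ms-locus genotype.

    Bands are matched to the reference sizes (~300 uncut, ~230 and ~70
    cut) within *tolerance_bp*; {300} -> MsMs, {300, 230, 70} -> Msms,
    {230, 70} -> msms. With ``low_band_dropout`` the faint ~70 bp fragment
    may be absent, so {300, 230} is accepted as Msms and {230} as msms.
    Anything else is an explicit no-call, never a silent guess.
    """
    bands = tuple(sorted(int(b) for b in bands))
    matched = set()
    unmatched = False
    for b in bands:
        hits = [k for k, ref in REFERENCE_BANDS.items() if abs(b - ref) <= tolerance_bp]
        if len(hits) == 1:
            matched.add(hits[0])
        else:
            unmatched = True
    genotype: str | None = None
    if not unmatched and matched:
        if matched == {"uncut"}:
            genotype = "MsMs"
        elif matched == {"uncut", "cut_long", "cut_short"}:
            genotype = "Msms"
        elif matched == {"cut_long", "cut_short"}:
            genotype = "msms"
        elif low_band_dropout and matched == {"uncut", "cut_long"}:
            genotype = "Msms"
        elif low_band_dropout and matched == {"cut_long"}:
            genotype = "msms"
    phenotype = None
    if genotype is not None:
        phenotype = "sterile" if genotype == "msms" else "fertile"
    return MsGenotypeCall(tuple(sorted(bands, reverse=True)), genotype, phenotype)


def assay_diploid(
    allele1: str,
    allele2: str,
    fwd: Primer = CIMYB80_FOR,
    rev: Primer = CIMYB80_REV,
    site: RestrictionSite = TRU1I,
    tolerance_bp: int = 15,
) -> MsGenotypeCall:
    """Full virtual assay on one diploid sample: PCR, digest both alleles,
    merge bands and call the genotype. Alleles without a productive
    amplicon yield a no-call."""
    amps1 = in_silico_pcr(allele1, fwd, rev, template_id="allele1")
    amps2 = in_silico_pcr(allele2, fwd, rev, template_id="allele2")
    if len(amps1) != 1 or len(amps2) != 1:
        return MsGenotypeCall((), None, None)
    bands = diploid_band_pattern(amps1[0].sequence, amps2[0].sequence, site)
    return call_ms_genotype(bands, tolerance_bp=tolerance_bp)


@dataclass
class ConcordanceResult:
    matches: int
    mismatches: int
    n_valid: int
    n_excluded: int  # pairs with a no-call on either side
    mismatch_pct: float  # on the 0-100 scale, 2-decimal half-up


def marker_concordance(calls_a: Sequence, calls_b: Sequence) -> ConcordanceResult:
    """Positional agreement between two paired genotype-call vectors.

    Pairs where either call is a no-call (None or empty string) are
    excluded from the percentage and counted separately.
    """
    from .popgen import round_half_up

    if len(calls_a) != len(calls_b):
        raise ValueError(
            f"call vectors differ in length: {len(calls_a)} vs {len(calls_b)}"
        )

    def valid(x) -> bool:
        if x is None or (isinstance(x, str) and x == ""):
            return False
        if isinstance(x, MsGenotypeCall):
            return not x.is_no_call
        return True

    def value(x):
        return x.genotype if isinstance(x, MsGenotypeCall) else x

    matches = mismatches = excluded = 0
    for a, b in zip(calls_a, calls_b):
        if not (valid(a) and valid(b)):
            excluded += 1
            continue
        if value(a) == value(b):
            matches += 1
        else:
            mismatches += 1
    n_valid = matches + mismatches
    pct = round_half_up(100 * mismatches / n_valid) if n_valid else float("nan")
    return ConcordanceResult(matches, mismatches, n_valid, excluded, pct)
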