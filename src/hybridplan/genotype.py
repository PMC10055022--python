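"""Data model and I/O for biallelic SNP genotype matrices.

Genotype calls are coded per individual and locus as

* ``0`` — homozygous for allele A,
* ``1`` — homozygous for allele B,
* ``2`` — heterozygous,
* ``MISSING`` (``-1``) — no call.

The same coding is shared by the diversity statistics, the AMOVA distance,
the similarity matrix and the Mendelian progeny predictions, so a dataset
loaded once feeds the entire pipeline.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call. Kept distinct from every valid code
#: because the completeness filter depends on it.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})
_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP locus (RADtag identifier plus SNP offset)."""

    locus_id: str
    allele_a: str = "A"
    allele_b: str = "C"
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.allele_a not in _NUCLEOTIDES or self.allele_b not in _NUCLEOTIDES:
            raise ValueError(
                f"locus {self.locus_id!r}: alleles must be A/C/G/T, "
                f"got {self.allele_a!r}/{self.allele_b!r}"
            )
        if self.allele_a == self.allele_b:
            raise ValueError(f"locus {self.locus_id!r}: alleles must differ")


@dataclass
class GenotypeDataset:
    """Samples x loci call matrix with a population label per sample.

    ``calls`` is an ``int8`` matrix of shape ``(n_samples, n_loci)`` holding
    the 0/1/2/MISSING codes. Sample and locus order is preserved from input
    everywhere so all downstream outputs are deterministic.
    """

    samples: list[str]
    populations: dict[str, str]
    loci: list[Locus]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        ids = [loc.locus_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids")
        missing_pop = [s for s in self.samples if s not in self.populations]
        if missing_pop:
            raise ValueError(f"samples without a population label: {missing_pop[:5]}")
        bad = set(np.unique(self.calls)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes in matrix: {sorted(bad)}")

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    def population_labels(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        if population not in set(self.populations.values()):
            raise KeyError(f"unknown population {population!r}")
        return [s for s in self.samples if self.populations[s] == population]

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def population_indices(self, population: str) -> np.ndarray:
        members = set(self.samples_in(population))
        return np.array([i for i, s in enumerate(self.samples) if s in members])

    def missing_fraction_per_sample(self) -> np.ndarray:
        if self.n_loci == 0:
            return np.zeros(self.n_samples)
        return np.mean(self.calls == MISSING, axis=1)

    def subset(
        self,
        samples: Sequence[str] | None = None,
        locus_mask: np.ndarray | None = None,
    ) -> "GenotypeDataset":
        """Return a new dataset restricted to the given samples/loci."""
        if samples is None:
            rows = np.arange(self.n_samples)
            keep_samples = list(self.samples)
        else:
            rows = np.array([self.sample_index(s) for s in samples])
            keep_samples = list(samples)
        if locus_mask is None:
            loci = list(self.loci)
            mat = self.calls[rows]
        else:
            locus_mask = np.asarray(locus_mask, dtype=bool)
            loci = [loc for loc, keep in zip(self.loci, locus_mask) if keep]
            mat = self.calls[np.ix_(rows, np.flatnonzero(locus_mask))]
        pops = {s: self.populations[s] for s in keep_samples}
        return GenotypeDataset(keep_samples, pops, loci, mat.copy())

    def allele_count_matrix(self) -> np.ndarray:
        """Allele-A copy number per sample and locus (2/0/1; MISSING -> -1).

        Codes map as 0 -> 2 copies of A, 1 -> 0 copies, 2 -> 1 copy. This is
        the additive encoding on which the squared genotypic distance and the
        simple-matching similarity both operate.
        """
        out = np.full(self.calls.shape, -1, dtype=np.int8)
        out[self.calls == 0] = 2
        out[self.calls == 1] = 0
        out[self.calls == 2] = 1
        return out


# ---------------------------------------------------------------------------
# Table I/O (canonical delimited-text dialect)
# ---------------------------------------------------------------------------

_SYMBOL_TO_CODE = {"0": 0, "1": 1, "2": 2, "NA": MISSING}
_CODE_TO_SYMBOL = {0: "0", 1: "1", 2: "2", MISSING: "NA"}


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_genotype_table(path, delimiter: str | None = None) -> GenotypeDataset:
    """Read the canonical genotype table.

    Layout: header ``sample,population,<locus ids...>``; one row per sample;
    calls in ``{0,1,2,NA}``. Both comma and tab dialects are accepted
    (auto-sniffed from the header when *delimiter* is None).
    """
    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first:
            raise ValueError(f"{path}: empty file")
        if delimiter is None:
            delimiter = _sniff_delimiter(first)
        header = next(csv.reader([first], delimiter=delimiter))
        if len(header) < 3 or header[0] != "sample" or header[1] != "population":
            raise ValueError(
                f"{path}: header must start with 'sample', 'population', got {header[:2]}"
            )
        locus_ids = header[2:]
        samples: list[str] = []
        pops: dict[str, str] = {}
        rows: list[list[int]] = []
        for lineno, rec in enumerate(csv.reader(fh, delimiter=delimiter), start=2):
            if not rec:
                continue
            if len(rec) != len(header):
                raise ValueError(
                    f"{path}: row {lineno} has {len(rec)} fields, expected {len(header)}"
                )
            sample = rec[0]
            samples.append(sample)
            pops[sample] = rec[1]
            codes = []
            for j, symbol in enumerate(rec[2:]):
                try:
                    codes.append(_SYMBOL_TO_CODE[symbol])
                except KeyError:
                    raise ValueError(
                        f"{path}: row {lineno}, locus {locus_ids[j]!r}: "
                        f"unknown call symbol {symbol!r}"
                    ) from None
            rows.append(codes)
    calls = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(locus_ids)), np.int8)
    loci = [Locus(lid) for lid in locus_ids]
    return GenotypeDataset(samples, pops, loci, calls)


def write_genotype_table(ds: GenotypeDataset, path, delimiter: str = ",") -> None:
    """Write the canonical table; inverse of :func:`read_genotype_table`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["sample", "population", *ds.locus_ids])
        for i, sample in enumerate(ds.samples):
            symbols = [_CODE_TO_SYMBOL[int(c)] for c in ds.calls[i]]
            writer.writerow([sample, ds.populations[sample], *symbols])


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------


def read_popmap(path) -> dict[str, str]:
    """Two-column TSV ``sample<TAB>population``."""
    popmap: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields")
            popmap[parts[0]] = parts[1]
    return popmap


def read_vcf_biallelic(path, popmap) -> GenotypeDataset:
    """Read biallelic SNP records from a VCF into a :class:`GenotypeDataset`.

    GT mapping: ``0/0 -> 0``, ``1/1 -> 1``, ``0/1``/``1/0 -> 2``,
    ``./. -> MISSING``. Records that are not biallelic SNPs are skipped and
    counted (logged). *popmap* may be a path to a TSV or a mapping.
    """
    from cyvcf2 import VCF  # deferred: htslib import is relatively heavy

    if not isinstance(popmap, Mapping):
        popmap = read_popmap(popmap)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in popmap]
    if absent:
        raise ValueError(f"samples present in VCF but absent from popmap: {absent}")
    loci: list[Locus] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    seen_ids: set[str] = set()
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1 \
                or var.REF not in _NUCLEOTIDES or alts[0] not in _NUCLEOTIDES:
            n_skipped += 1
            continue
        locus_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        if locus_id in seen_ids:
            locus_id = f"{locus_id}_{len(loci)}"
        seen_ids.add(locus_id)
        loci.append(Locus(locus_id, allele_a=var.REF, allele_b=alts[0]))
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        col = np.full(len(samples), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 3] = 1
        col[gt == 1] = 2
        cols.append(col)
    if n_skipped:
        logger.info("read_vcf_biallelic: skipped %d non-biallelic-SNP records", n_skipped)
    calls = np.column_stack(cols) if cols else np.empty((len(samples), 0), np.int8)
    pops = {s: popmap[s] for s in samples}
    ds = GenotypeDataset(samples, pops, loci, calls)
    ds.n_excluded_records = n_skipped  # type: ignore[attr-defined]
    return ds


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def drop_high_missing_samples(
    ds: GenotypeDataset, max_missing_fraction: float = 0.2
) -> GenotypeDataset:
    """Remove samples whose missing-call fraction exceeds the threshold.

    Emulates the QC step that excluded poorly sequenced individuals before
    analysis. Removals are logged per sample; the returned dataset records
    them in ``removed_samples``.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError(f"max_missing_fraction must be in [0,1], got {max_missing_fraction}")
    frac = ds.missing_fraction_per_sample()
    removed = [s for s, f in zip(ds.samples, frac) if f > max_missing_fraction]
    for s, f in zip(ds.samples, frac):
        if f > max_missing_fraction:
            logger.info("dropping sample %s: %.1f%% missing calls", s, 100 * f)
    kept = [s for s in ds.samples if s not in set(removed)]
    out = ds.subset(samples=kept)
    out.removed_samples = removed  # type: ignore[attr-defined]
    return out


def filter_complete_loci(ds: GenotypeDataset) -> GenotypeDataset:
    """Keep only loci with zero missing calls across all samples.

    Complete-call loci are the basis of every downstream statistic; the
    filter is idempotent and preserves locus order.
    """
    mask = ~(ds.calls == MISSING).any(axis=0)
    return ds.subset(locus_mask=mask)


# ---------------------------------------------------------------------------
# Allele bookkeeping
# ---------------------------------------------------------------------------


def allele_counts(
    ds: GenotypeDataset, locus: str, population: str | None = None
) -> tuple[int, int, int]:
    """Copies of allele A, copies of allele B and genotyped sample count.

    ``countA + countB == 2 * n`` always holds; restricted to *population*
    when given.
    """
    try:
        j = ds.locus_ids.index(locus)
    except ValueError:
        raise KeyError(f"unknown locus {locus!r}") from None
    col = ds.calls[:, j]
    if population is not None:
        col = col[ds.population_indices(population)]
    col = col[col != MISSING]
    n = int(col.size)
    count_a = int(2 * np.sum(col == 0) + np.sum(col == 2))
    count_b = int(2 * np.sum(col == 1) + np.sum(col == 2))
    return count_a, count_b, n
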