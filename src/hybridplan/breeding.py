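"""Parental selection and Mendelian prediction of progeny heterozygosity.

For a biallelic locus, the expected heterozygote frequency among offspring
of two parents follows directly from Mendelian segregation:

* both parents the same homozygote  -> 0
* opposite homozygotes              -> 1
* any pairing involving a heterozygote -> 0.5

Loci are treated as independent, so the genome-wide expectation is the mean
of per-locus values; for single-generation means this is exact regardless
of linkage. Three mating strategies are compared: selfing (S), full-sib
crossing within a population (FS) and pairwise crossing between
populations (F1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeDataset
from .similarity import SimilarityMatrix


def expected_progeny_het_locus(g1: int, g2: int) -> float:
    """Expected heterozygote frequency in the progeny at one locus."""
    if g1 not in (0, 1, 2) or g2 not in (0, 1, 2):
        raise ValueError(f"genotype codes must be 0/1/2, got ({g1}, {g2})")
    if g1 == 2 or g2 == 2:
        return 0.5
    return 0.0 if g1 == g2 else 1.0


def _pair_het_profile(calls1: np.ndarray, calls2: np.ndarray) -> np.ndarray:
    """Vectorised per-locus expected progeny heterozygosity for one pair."""
    het = (calls1 == 2) | (calls2 == 2)
    out = np.where(het, 0.5, np.where(calls1 != calls2, 1.0, 0.0))
    return out


def expected_progeny_heterozygosity(
    ds: GenotypeDataset, parent1: str, parent2: str
) -> float:
    """Mean expected progeny heterozygosity over all loci for one cross.

    ``parent1 == parent2`` encodes selfing, for which the result equals
    half the parent's own heterozygosity exactly.
    """
    i = ds.sample_index(parent1)
    j = ds.sample_index(parent2)
    c1, c2 = ds.calls[i], ds.calls[j]
    if (c1 == MISSING).any() or (c2 == MISSING).any():
        raise ValueError("parents have missing calls; run filter_complete_loci first")
    return float(_pair_het_profile(c1, c2).mean())


@dataclass
class SelectionResult:
    """Selected parents for one population."""

    population: str
    selected: list[str]
    relaxed: bool  # GS-cohesion threshold had to be relaxed to reach k
    shortfall: int  # requested minus available


def select_parents(
    ds: GenotypeDataset,
    sim: SimilarityMatrix,
    hom: pd.Series,
    k: int = 10,
    gs_threshold: float = 0.90,
) -> dict[str, SelectionResult]:
    """Pick up to *k* elite parents per population.

    Greedy per population: candidates are ranked by observed homozygosity
    (descending, ties by input order); the top-ranked seeds the set, then
    the highest-homozygosity candidate whose GS to every already-selected
    parent exceeds *gs_threshold* is added repeatedly. If fewer than *k*
    qualify, the remaining slots are filled in homozygosity order with the
    ``relaxed`` flag set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    id_index = {s: i for i, s in enumerate(sim.sample_ids)}
    out: dict[str, SelectionResult] = {}
    for pop in ds.population_labels():
        members = ds.samples_in(pop)
        order = sorted(range(len(members)), key=lambda i: (-hom[members[i]], i))
        ranked = [members[i] for i in order]
        target = min(k, len(members))
        selected: list[str] = [ranked[0]]
        remaining = ranked[1:]
        relaxed = False
        while len(selected) < target:
            pick = None
            for cand in remaining:
                ci = id_index[cand]
                if all(sim.matrix[ci, id_index[s]] > gs_threshold for s in selected):
                    pick = cand
                    break
            if pick is None:
                pick = remaining[0]
                relaxed = True
            selected.append(pick)
            remaining.remove(pick)
        out[pop] = SelectionResult(
            population=pop,
            selected=selected,
            relaxed=relaxed,
            shortfall=max(0, k - len(members)),
        )
    return out


@dataclass
class CrossPredictionMatrix:
    """Square parent-by-parent matrix of GS and predicted progeny He.

    ``matrix[i, j]`` holds genetic similarity below the diagonal and
    expected progeny heterozygosity above it; the diagonal stores the
    selfing prediction (half the parent's heterozygosity). Per-parent
    observed homozygosity is carried alongside as the diagonal margin.
    """

    parent_ids: list[str]
    parent_pops: list[str]
    matrix: np.ndarray = field(repr=False)
    homozygosity: np.ndarray = field(repr=False)

    def strategy(self, i: int, j: int) -> str:
        if i == j:
            return "S"
        return "FS" if self.parent_pops[i] == self.parent_pops[j] else "F1"

    def gs(self, i: int, j: int) -> float:
        lo, hi = sorted((i, j))
        return float(self.matrix[hi, lo])

    def progeny_he(self, i: int, j: int) -> float:
        lo, hi = sorted((i, j))
        return float(self.matrix[lo, hi]) if lo != hi else float(self.matrix[lo, lo])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.parent_ids, columns=self.parent_ids)


def cross_prediction_matrix(
    ds: GenotypeDataset, selected_parents
) -> CrossPredictionMatrix:
    """Build the GS-below / progeny-He-above matrix over selected parents.

    *selected_parents* is either a flat list of sample ids or the mapping
    returned by :func:`select_parents`; population blocks keep input order.
    """
    if isinstance(selected_parents, dict):
        parents = [s for res in selected_parents.values() for s in res.selected]
    else:
        parents = list(selected_parents)
    if len(set(parents)) != len(parents):
        raise ValueError("duplicate parent ids")
    sub = ds.subset(samples=parents)
    from .similarity import observed_homozygosity, simple_matching_gs

    gs = simple_matching_gs(sub).matrix
    hom = observed_homozygosity(sub).to_numpy()
    n = len(parents)
    mat = np.zeros((n, n))
    counts = sub.calls
    for i in range(n):
        mat[i, i] = _pair_het_profile(counts[i], counts[i]).mean()  # selfing
        for j in range(i + 1, n):
            mat[i, j] = _pair_het_profile(counts[i], counts[j]).mean()
            mat[j, i] = gs[i, j]
    pops = [sub.populations[s] for s in parents]
    return CrossPredictionMatrix(parents, pops, mat, hom)


def strategy_summary(cpm: CrossPredictionMatrix) -> pd.DataFrame:
    """Distribution of predicted progeny He per mating strategy.

    One row per population for selfing (S: each parent selfed) and
    full-sib crossing (FS: all within-population pairs), and one row per
    population pair for F1 crosses. Quartiles use linear interpolation.
    Empty categories are omitted.
    """
    n = len(cpm.parent_ids)
    groups: dict[tuple[str, str], list[float]] = {}
    for i in range(n):
        groups.setdefault(("S", cpm.parent_pops[i]), []).append(cpm.progeny_he(i, i))
        for j in range(i + 1, n):
            pi, pj = cpm.parent_pops[i], cpm.parent_pops[j]
            if pi == pj:
                key = ("FS", pi)
            else:
                key = ("F1", f"{pi}x{pj}")
            groups.setdefault(key, []).append(cpm.progeny_he(i, j))
    rows = []
    for (strategy, group), vals in groups.items():
        arr = np.asarray(vals)
        rows.append(
            {
                "strategy": strategy,
                "group": group,
                "n": arr.size,
                "min": arr.min(),
                "q1": float(np.quantile(arr, 0.25)),
                "median": float(np.quantile(arr, 0.5)),
                "mean": float(arr.mean()),
                "q3": float(np.quantile(arr, 0.75)),
                "max": arr.max(),
            }
        )
    return pd.DataFrame(rows)
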