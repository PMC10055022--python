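"""Per-population diversity statistics, Wright's F-statistics and Evanno dK.

The summary-table conventions follow the GenAlEx lineage of population
genetics software: expected heterozygosity is the uncorrected 2pq, and the
fixation indices are means of per-locus ratios over loci where the
denominator is positive (not ratios of means). Percentages are reported on
the 0-100 scale with half-up rounding at presentation time only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeDataset


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as the printed tables do."""
    x = float(x)
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def allele_frequencies(ds: GenotypeDataset, population: str) -> np.ndarray:
    """Per-locus frequency of allele A within one population.

    Loci with no genotyped individuals are returned as NaN (undefined).
    """
    rows = ds.population_indices(population)
    sub = ds.calls[rows]
    n = np.sum(sub != MISSING, axis=0).astype(float)
    count_a = 2 * np.sum(sub == 0, axis=0) + np.sum(sub == 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, count_a / (2 * n), np.nan)
    return p


def _pop_freq_het(ds: GenotypeDataset):
    """(k x L) allele-A frequencies and observed-het fractions per population."""
    pops = ds.population_labels()
    p = np.vstack([allele_frequencies(ds, pop) for pop in pops])
    ho = []
    for pop in pops:
        sub = ds.calls[ds.population_indices(pop)]
        n = np.sum(sub != MISSING, axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho.append(np.where(n > 0, np.sum(sub == 2, axis=0) / n, np.nan))
    return pops, p, np.vstack(ho)


def population_summary(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-population diversity statistics plus an unweighted mean row.

    Columns: N, na (mean observed alleles/locus), ne (mean effective
    alleles/locus, 1/(p^2+q^2)), Ho and He as percentages, F (mean of
    per-locus (He-Ho)/He over polymorphic loci), PL_pct (% polymorphic
    loci), PA_count (private alleles) and PA_pct (private alleles as a
    percentage of all alleles observed in the population).
    """
    if ds.n_loci == 0:
        raise ValueError("dataset has no loci")
    pops, p, ho = _pop_freq_het(ds)
    if any(len(ds.samples_in(pop)) == 0 for pop in pops):
        raise ValueError("empty population")
    q = 1.0 - p
    present_a = p > 0
    present_b = q > 0
    na = present_a.astype(float) + present_b.astype(float)  # k x L
    ne = 1.0 / (p**2 + q**2)
    he = 2 * p * q
    poly = present_a & present_b

    # private alleles: allele present in this population, absent in all others
    k = len(pops)
    rows = []
    for i, pop in enumerate(pops):
        others = [j for j in range(k) if j != i]
        priv_a = present_a[i] & ~present_a[others].any(axis=0)
        priv_b = present_b[i] & ~present_b[others].any(axis=0)
        pa_count = int(priv_a.sum() + priv_b.sum())
        total_alleles = float(na[i].sum())
        he_i = he[i]
        ho_i = ho[i]
        poly_i = he_i > 0
        if poly_i.any():
            f_mean = float(np.mean((he_i[poly_i] - ho_i[poly_i]) / he_i[poly_i]))
        else:
            f_mean = math.nan
        rows.append(
            {
                "population": pop,
                "N": float(len(ds.samples_in(pop))),
                "na": float(np.nanmean(na[i])),
                "ne": float(np.nanmean(ne[i])),
                "Ho": float(np.nanmean(ho_i)) * 100,
                "He": float(np.nanmean(he_i)) * 100,
                "F": f_mean,
                "PL_pct": float(np.nanmean(poly[i])) * 100,
                "PA_count": pa_count,
                "PA_pct": 100 * pa_count / total_alleles if total_alleles else 0.0,
            }
        )
    df = pd.DataFrame(rows).set_index("population")
    df.loc["Mean"] = df.mean(axis=0)
    return df


def mean_row(values) -> float:
    """Unweighted mean of per-population values, printed-table rounding."""
    return round_half_up(float(np.mean(np.asarray(values, dtype=float))))


@dataclass
class FStatistics:
    """Collection-wide heterozygosity partition and fixation indices.

    ``hs``/``ht`` are means over loci of the within-population and total
    expected heterozygosity (unweighted over populations); ``fis``, ``fit``
    and ``fst`` are means of per-locus ratios. ``nm`` is the island-model
    gene-flow estimate 0.25(1-Fst)/Fst from the mean Fst. ``theta_hat`` is
    a bias-corrected estimator of the divergence parameter: the
    Nei-Chesser sample-size-corrected Gst computed as a ratio of sums over
    loci, de-biased for the finite number of populations surveyed
    (Gst estimates theta(1-1/k)/(1-theta/k) for k populations, inverted).
    """

    hs: float
    ht: float
    fis: float
    fit: float
    fst: float
    nm: float
    se_hs: float
    se_ht: float
    se_fis: float
    se_fit: float
    se_fst: float
    n_loci: int
    n_populations: int
    theta_hat: float


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return math.nan, math.nan
    se = float(np.std(values, ddof=1) / math.sqrt(values.size)) if values.size > 1 else 0.0
    return float(values.mean()), se


def f_statistics(ds: GenotypeDataset) -> FStatistics:
    """Wright's F-statistics and gene flow across all populations."""
    pops, p, ho = _pop_freq_het(ds)
    k = len(pops)
    if k < 2:
        raise ValueError("F-statistics require at least 2 populations")
    hs_l = np.nanmean(2 * p * (1 - p), axis=0)
    pbar = np.nanmean(p, axis=0)
    ht_l = 2 * pbar * (1 - pbar)
    hobar_l = np.nanmean(ho, axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        fis_l = np.where(hs_l > 0, (hs_l - hobar_l) / hs_l, np.nan)
        fit_l = np.where(ht_l > 0, (ht_l - hobar_l) / ht_l, np.nan)
        fst_l = np.where(ht_l > 0, (ht_l - hs_l) / ht_l, np.nan)

    hs, se_hs = _mean_se(hs_l)
    ht, se_ht = _mean_se(ht_l)
    fis, se_fis = _mean_se(fis_l)
    fit, se_fit = _mean_se(fit_l)
    fst, se_fst = _mean_se(fst_l)
    nm = 0.25 * (1 - fst) / fst if fst > 0 else math.inf

    # parameter-recovery estimator: Nei-Chesser corrected Gst as a ratio of
    # sums, then inverted for the finite number of surveyed populations
    n_harm = k / np.sum([1 / len(ds.samples_in(pop)) for pop in pops])
    hs_u = (2 * n_harm / (2 * n_harm - 1)) * hs_l
    ht_u = ht_l + hs_u / (2 * n_harm * k)
    ok = ht_u > 0
    gst = float((ht_u[ok] - hs_u[ok]).sum() / ht_u[ok].sum()) if ok.any() else math.nan
    theta_hat = gst / ((1 - 1 / k) + gst / k) if math.isfinite(gst) else math.nan

    return FStatistics(
        hs=hs, ht=ht, fis=fis, fit=fit, fst=fst, nm=nm,
        se_hs=se_hs, se_ht=se_ht, se_fis=se_fis, se_fit=se_fit, se_fst=se_fst,
        n_loci=ds.n_loci, n_populations=k, theta_hat=theta_hat,
    )


# ---------------------------------------------------------------------------
# Evanno delta-K from admixture-run log-likelihood summaries
# ---------------------------------------------------------------------------


def read_lnp_table(path) -> pd.DataFrame:
    """TSV ``K<TAB>replicate<TAB>lnP`` (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [c.lower() for c in df.columns]
    if "k" in cols and "lnp" in cols:
        df.columns = cols
    else:  # headerless export
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df.columns = ["k", "replicate", "lnp"][: df.shape[1]]
    return df[["k", "replicate", "lnp"]].astype({"k": int})


def evanno_delta_k(lnp_table: pd.DataFrame) -> pd.DataFrame:
    """Evanno's second-order rate-of-change statistic for choosing K.

    *lnp_table* holds one row per (K, replicate) with the admixture model's
    log-likelihood. Returns one row per K with mean/sd of L(K), the first
    difference L'(K) = L(K) - L(K-1) on replicate means, |L''(K)| and
    deltaK = |L''(K)| / sd(L(K)). Endpoint K values and K with sd = 0 have
    undefined deltaK (NaN, flagged). ``best_k`` is attached in ``attrs``.
    """
    df = lnp_table.rename(columns={c: c.lower() for c in lnp_table.columns})
    if not {"k", "lnp"} <= set(df.columns):
        raise ValueError("expected columns K and lnP")
    grouped = df.groupby("k")["lnp"]
    ks = np.array(sorted(grouped.groups))
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if not np.all(np.diff(ks) == 1):
        raise ValueError(f"K values must be consecutive, got {list(ks)}")
    counts = grouped.count().reindex(ks)
    if (counts < 2).any():
        raise ValueError("need at least 2 replicates per K")
    mean_l = grouped.mean().reindex(ks).to_numpy()
    sd_l = grouped.std(ddof=1).reindex(ks).to_numpy()

    lprime = np.full(len(ks), np.nan)
    lprime[1:] = np.diff(mean_l)
    ldpp = np.full(len(ks), np.nan)
    ldpp[1:-1] = np.abs(mean_l[2:] - 2 * mean_l[1:-1] + mean_l[:-2])
    with np.errstate(invalid="ignore", divide="ignore"):
        delta_k = np.where(sd_l > 0, ldpp / sd_l, np.nan)
    delta_k[[0, -1]] = np.nan

    out = pd.DataFrame(
        {
            "K": ks,
            "mean_lnP": mean_l,
            "sd_lnP": sd_l,
            "Lprime": lprime,
            "Ldoubleprime_abs": ldpp,
            "deltaK": delta_k,
            "undefined": ~np.isfinite(delta_k),
        }
    ).set_index("K")
    defined = out["deltaK"].dropna()
    out.attrs["best_k"] = int(defined.idxmax()) if len(defined) else None
    return out
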