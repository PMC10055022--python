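"""End-to-end analysis pipeline: import, filter, statistics, clustering,
parental selection, cross prediction and (optionally) the CAPS assay, with
a reproducibility manifest.

Every stage output is a pure function of the inputs, the configuration and
the seeds; the manifest records SHA-256 checksums of every written file so
a rerun can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amova import amova
from .breeding import cross_prediction_matrix, select_parents, strategy_summary
from .genotype import (
    GenotypeDataset,
    drop_high_missing_samples,
    filter_complete_loci,
    read_genotype_table,
    read_vcf_biallelic,
    write_genotype_table,
)
from .popgen import f_statistics, population_summary, round_half_up
from .similarity import (
    group_similarity_summary,
    observed_homozygosity,
    pcoa,
    simple_matching_gs,
    upgma,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serialisable configuration of one pipeline run."""

    table: str | None = None
    vcf: str | None = None
    popmap: str | None = None
    out_dir: str = "hybridplan_out"
    max_missing_fraction: float = 0.2
    amova_permutations: int = 999
    amova_seed: int = 1
    selection_k: int = 10
    gs_threshold: float = 0.90
    pcoa_axes: int = 2


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_pct_csv(df: pd.DataFrame, path: Path, pct_columns=()) -> None:
    out = df.copy()
    for col in pct_columns:
        if col in out.columns:
            out[col] = out[col].map(lambda x: round_half_up(x) if pd.notna(x) else x)
    out.to_csv(path)


def run_pipeline(config: RunConfig, dataset: GenotypeDataset | None = None) -> dict:
    """Run every stage and write the report bundle into ``config.out_dir``.

    *dataset* may be passed directly (e.g. a synthetic cohort); otherwise
    the table or VCF named in the config is loaded. Returns the manifest.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "import"
    try:
        if dataset is not None:
            ds = dataset
        elif config.table:
            ds = read_genotype_table(config.table)
        elif config.vcf:
            if not config.popmap:
                raise ValueError("VCF input requires a popmap")
            ds = read_vcf_biallelic(config.vcf, config.popmap)
        else:
            raise ValueError("no input: provide a dataset, table or vcf")

        stage = "filter"
        ds = drop_high_missing_samples(ds, config.max_missing_fraction)
        n_before = ds.n_loci
        ds = filter_complete_loci(ds)
        logger.info("filter: retained %d of %d loci with complete calls", ds.n_loci, n_before)
        write_genotype_table(ds, out_dir / "filtered_genotypes.csv")

        stage = "stats"
        summary = population_summary(ds)
        _write_pct_csv(summary, out_dir / "population_stats.csv",
                       pct_columns=("Ho", "He", "PL_pct", "PA_pct"))
        fstats = f_statistics(ds)
        pd.DataFrame([vars(fstats)]).to_csv(out_dir / "f_statistics.csv", index=False)

        stage = "amova"
        res = amova(ds, n_permutations=config.amova_permutations, seed=config.amova_seed)
        pd.DataFrame(
            [
                {"source": "Among Pops", "df": res.df_among, "SS": res.ss_among,
                 "MS": res.ms_among, "est_var": res.var_among, "pct": round_half_up(res.pct_among)},
                {"source": "Within Pops", "df": res.df_within, "SS": res.ss_within,
                 "MS": res.ms_within, "est_var": res.var_within, "pct": round_half_up(res.pct_within)},
                {"source": "Total", "df": res.df_total, "SS": res.ss_total,
                 "MS": np.nan, "est_var": res.var_total, "pct": 100.0},
            ]
        ).to_csv(out_dir / "amova.csv", index=False)
        (out_dir / "amova_test.json").write_text(
            json.dumps({"phi_pt": res.phi_pt, "p_value": res.p_value,
                        "n_permutations": res.n_permutations}, indent=2)
        )

        stage = "similarity"
        sim = simple_matching_gs(ds)
        sim.to_dataframe().to_csv(out_dir / "gs_matrix.csv")
        hom = observed_homozygosity(ds)
        hom.to_csv(out_dir / "homozygosity.csv")
        gss = group_similarity_summary(sim, hom, ds.populations)
        gss.within.to_csv(out_dir / "gs_within.csv")
        gss.among.to_csv(out_dir / "gs_among.csv", index=False)
        gss.homozygosity.to_csv(out_dir / "homozygosity_by_pop.csv")

        stage = "tree"
        tree = upgma(sim)
        (out_dir / "upgma.nwk").write_text(tree.to_newick() + "\n")

        stage = "pcoa"
        emb = pcoa(sim, n_axes=config.pcoa_axes)
        emb.to_dataframe().to_csv(out_dir / "pcoa_coordinates.csv")
        pd.DataFrame(
            {"axis": np.arange(1, len(emb.pct_variance) + 1), "pct_variance": emb.pct_variance}
        ).to_csv(out_dir / "pcoa_variance.csv", index=False)

        stage = "select-parents"
        selection = select_parents(ds, sim, hom, k=config.selection_k,
                                   gs_threshold=config.gs_threshold)
        pd.DataFrame(
            [
                {"population": pop, "sample": s, "rank": r + 1,
                 "relaxed": sel.relaxed, "shortfall": sel.shortfall}
                for pop, sel in selection.items()
                for r, s in enumerate(sel.selected)
            ]
        ).to_csv(out_dir / "selected_parents.csv", index=False)

        stage = "predict-cross"
        cpm = cross_prediction_matrix(ds, selection)
        cpm.to_dataframe().to_csv(out_dir / "cross_prediction_matrix.csv")

        stage = "strategy-summary"
        strategy_summary(cpm).to_csv(out_dir / "strategy_summary.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage = "manifest"
    outputs = sorted(p for p in out_dir.iterdir() if p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "n_samples": ds.n_samples,
        "n_loci": ds.n_loci,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
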