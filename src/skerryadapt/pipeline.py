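"""End-to-end orchestration: simulate -> filter -> stats -> demography ->
envelope -> karyotype -> phenotype fits, with a reproducibility manifest.

Every stage reads only its declared inputs, draws randomness only from the
configured seeds, and records its outputs in a JSON manifest, so a rerun
with the same configuration reproduces all stochastic outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import envelope as env
from . import filters as flt
from . import inversions as inv
from . import phenotypes as phe
from . import popgen as pg
from .core_model import DemographicParams
from .likelihood import grid_search, refine_and_support_limits
from .simulate import (
    ScenarioConfig,
    generate_genetic_dataset,
    generate_phenotype_dataset,
)

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_GRID"]

logger = logging.getLogger(__name__)

#: Shipped default grid: founder sizes up to the transplanted ~700 adults,
#: K consistent with ~2000 snails (haploid counts), migrants capped at 8
#: haploid genomes per generation, f spanning plausible generation times.
DEFAULT_GRID = {
    "n0": [20, 60, 100, 200],
    "r": [0.1, 0.2, 0.3, 0.45, 0.6],
    "k": [600, 1200, 2000, 4000],
    "m": [0, 1, 2, 3, 4, 5, 6, 8],
    "f": [1, 1.5, 2, 2.5, 3],
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "filter": True, "stats": True,
        "infer_demography": True, "envelope": True,
        "karyotype": True, "phenofit": True,
    })
    genotypes: str | None = None  # inputs; filled by the simulate stage
    snp_map: str | None = None
    phenotypes: str | None = None
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    grid: dict = field(default_factory=lambda: {
        "n0": [60], "k": [300], "f": [2],
        "r": [0.1, 0.2, 0.3, 0.45, 0.6],
        "m": [0, 1, 2, 3, 4, 5, 6],
    })
    fix_f: float | None = None
    envelope_reps: int = 500
    mcmc_iters: int = 3000
    mcmc_burnin: int = 1000
    trait_priors: dict = field(default_factory=dict)  # trait -> {p: (mu, sd), v_g: (mu, sd)}

    GENOTYPE_STAGES = ("filter", "stats", "infer_demography", "envelope", "karyotype")

    def needs_genotypes(self) -> bool:
        return any(self.stages.get(s, False) for s in self.GENOTYPE_STAGES)

    def validate(self) -> None:
        if self.stages.get("simulate", False):
            return
        if self.needs_genotypes():
            for name in ("genotypes", "snp_map"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(
                        f"stage inputs unresolvable: {name} missing ({path})"
                    )
        if self.stages.get("phenofit", False) and (
            self.phenotypes is None or not Path(self.phenotypes).exists()
        ):
            raise FileNotFoundError(
                f"stage inputs unresolvable: phenotypes missing ({self.phenotypes})"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        return str(o)

    path.write_text(json.dumps(obj, indent=1, default=default))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "inputs": {},
    }

    def record(stage: str, outputs: dict) -> None:
        manifest["stages"][stage] = {"status": "completed", **outputs}

    def skip(stage: str) -> bool:
        if config.stages.get(stage, False):
            return False
        manifest["stages"][stage] = {"status": "skipped"}
        return True

    # ------------------------------------------------------------- simulate
    truth = None
    if not skip("simulate"):
        ds = generate_genetic_dataset(config.scenario, seed=config.seed)
        pheno, pheno_truth = generate_phenotype_dataset(
            config.scenario, seed=config.seed + 1
        )
        gpath, mpath, ppath = out / "genotypes.csv", out / "map.tsv", out / "phenotypes.csv"
        flt.write_genotype_csv(ds.genotypes, str(gpath))
        ds.snp_map.to_csv(mpath, sep="\t", index=False)
        pheno.to_csv(ppath, index=False)
        truth = {**{k: v for k, v in ds.truth.items() if k != "loci"},
                 "phenotypes": pheno_truth}
        truth["loci"] = ds.truth["loci"].to_dict(orient="list")
        # karyotype truth keys are tuples; stringify for JSON
        for name in truth.get("inversions", {}):
            kt = truth["inversions"][name]["karyotypes"]
            truth["inversions"][name]["karyotypes"] = {
                k: list(v) for k, v in kt.items()
            }
        _write_json(truth, out / "truth.json")
        config.genotypes, config.snp_map = str(gpath), str(mpath)
        config.phenotypes = str(ppath)
        record("simulate", {"genotypes": str(gpath), "snp_map": str(mpath),
                            "phenotypes": str(ppath)})

    geno = snp_map = None
    collinear = controls = outliers = []
    if config.needs_genotypes():
        geno = flt.read_genotype_csv(config.genotypes)
        snp_map = flt.read_snp_map(config.snp_map)
        manifest["inputs"] = {
            "genotypes": _sha256(Path(config.genotypes)),
            "snp_map": _sha256(Path(config.snp_map)),
        }
        collinear = snp_map.loc[
            snp_map["category"].isin(["control", "spatial_outlier"]), "snp_id"
        ].tolist()
        controls = snp_map.loc[snp_map["category"] == "control", "snp_id"].tolist()
        outliers = snp_map.loc[snp_map["category"] == "spatial_outlier", "snp_id"].tolist()

    # --------------------------------------------------------------- filter
    freq = None
    if not skip("filter"):
        res = flt.population_missingness_filter(
            geno[list(flt.META_COLUMNS) + collinear], context="pca_collinear"
        )
        freq = pg.allele_frequency_table(geno, collinear)
        fpath = out / "allele_frequencies.tsv"
        freq.to_csv(fpath, sep="\t", index=False)
        _write_json(
            {"removed_individuals": res.removed_individuals,
             "removed_snps": res.removed_snps,
             "flagged_groups": res.flagged_groups},
            out / "filter_log.json",
        )
        record("filter", {"allele_frequencies": str(fpath)})

    if freq is None and geno is not None and collinear:
        freq = pg.allele_frequency_table(geno, collinear)

    def year_freqs(pop: str, years) -> pd.Series:
        sub = freq[(freq["population"] == pop) & (freq["year"].isin(list(years)))]
        sub = sub.dropna(subset=["frequency"])
        return sub.groupby("locus").apply(
            lambda g: np.average(g["frequency"], weights=g["n_individuals"]),
            include_groups=False,
        )

    # ---------------------------------------------------------------- stats
    if not skip("stats"):
        p92 = year_freqs("crab", [1992])
        pwave = year_freqs("wave", [2018, 2021])
        rows = []
        for year in (2005, 2018, 2021):
            pt = year_freqs("skerry", [year])
            for cat, ids in (("control", controls), ("spatial_outlier", outliers)):
                sel = [i for i in ids if i in p92.index and i in pt.index and i in pwave.index]
                if not sel:
                    continue
                frac, n_exc = pg.fraction_shifted_toward_wave(
                    p92[sel].to_numpy(), pt[sel].to_numpy(), pwave[sel].to_numpy()
                )
                rows.append({"year": year, "category": cat,
                             "fraction_toward_wave": frac, "n_excluded": n_exc})
        shift = pd.DataFrame(rows)
        spath = out / "shift_fractions.tsv"
        shift.to_csv(spath, sep="\t", index=False)

        # signed temporal vs spatial differentiation for outlier loci
        p21 = year_freqs("skerry", [2021])
        pcrab = year_freqs("crab", [2018, 2021])
        records = []
        for loc in outliers:
            if not all(loc in s.index for s in (p92, p21, pcrab, pwave)):
                continue
            t = pg.signed_temporal_fst(p92[loc], p21[loc], pcrab[loc], pwave[loc])
            sp = pg.fst(pcrab[loc], pwave[loc])
            if np.isfinite(t) and np.isfinite(sp):
                records.append(pg.SignedFstRecord(loc, t, sp))
        summary: dict = {}
        if len(records) >= 5:
            rho, p = pg.space_time_correlation(records)
            summary["spearman_rho"], summary["spearman_p"] = rho, p
        pd.DataFrame([asdict(r) for r in records]).to_csv(
            out / "signed_fst.tsv", sep="\t", index=False
        )
        _write_json(summary, out / "stats_summary.json")
        record("stats", {"shift_fractions": str(spath)})

    # --------------------------------------------------- demographic inference
    surface = None
    if not skip("infer_demography"):
        series = flt.sample_series_from_genotypes(geno, controls, seed=config.seed)
        surface = grid_search(config.grid, series, fixed_f=config.fix_f)
        for parameter in ("r", "m"):
            if len(set(config.grid.get(parameter, []))) >= 4:
                refine_and_support_limits(surface, parameter)
        tpath = out / "surface.tsv"
        surface.table.to_csv(tpath, sep="\t", index=False)
        best = surface.best_params
        _write_json(
            {"best": asdict(best),
             "best_m_diploid": best.m_diploid,
             "interpolated_best": surface.interpolated_best,
             "support_intervals": {
                 k: [v.lower, v.upper] for k, v in surface.support_intervals.items()
             }},
            out / "demography.json",
        )
        record("infer_demography", {"surface": str(tpath)})

    # ------------------------------------------------------------- envelope
    if not skip("envelope"):
        if surface is None:
            raise RuntimeError("stage envelope requires infer_demography [E_STAGE]")
        series = flt.sample_series_from_genotypes(
            geno, controls + outliers, seed=config.seed
        )
        rows = []
        for j, s in enumerate(series):
            er = env.expected_range_for_locus(
                s, surface, n_reps=config.envelope_reps,
                seed=env.locus_rng(config.seed, j),
            )
            cls = env.classify_locus(
                er, s.p_wave, s.observed_counts[0] / s.sample_sizes[0]
            )
            rows.append({
                "locus": s.locus, "q025": er.q025, "median": er.median,
                "q975": er.q975, "observed_change": er.observed_change,
                "outside_range": cls.outside_range,
                "toward_wave": cls.toward_wave,
                "above_median": cls.above_median,
            })
        epath = out / "envelope.tsv"
        pd.DataFrame(rows).to_csv(epath, sep="\t", index=False)
        record("envelope", {"envelope": str(epath),
                            "n_reps": config.envelope_reps})

    # ------------------------------------------------------------ karyotype
    if not skip("karyotype"):
        inv_defs = []
        if "inversion" in snp_map.columns:
            diag_rows = snp_map[snp_map["category"] == "inversion_diagnostic"]
            for name, grp in diag_rows.groupby("inversion"):
                if not name:
                    continue
                complexity = str(grp["complexity"].iloc[0]) if "complexity" in grp else "simple"
                inv_defs.append((name, tuple(grp["snp_id"]), complexity))
        outputs = {}
        for name, snps, complexity in inv_defs:
            cols = list(flt.META_COLUMNS) + list(snps)
            res = flt.population_missingness_filter(geno[cols], context="inversion")
            present = [s for s in snps if s in res.imputed.columns]
            idef = inv.InversionDef(name=str(name), snp_ids=tuple(present),
                                    complexity=complexity)
            table, diag = inv.karyotype_individuals(
                res.imputed, idef, seed=config.seed
            )
            ftable, wave_arr = inv.arrangement_frequencies(
                table, geno[["individual", "population", "year"]]
            )
            kpath = out / f"karyotypes_{name}.tsv"
            apath = out / f"arrangements_{name}.tsv"
            table.to_csv(kpath, sep="\t", index=False)
            ftable.to_csv(apath, sep="\t", index=False)
            outputs[str(name)] = {
                "karyotypes": str(kpath), "arrangements": str(apath),
                "wave_arrangement": wave_arr, "silhouette": diag["silhouette"],
            }
        record("karyotype", outputs)

    # -------------------------------------------------------------- phenofit
    if not skip("phenofit"):
        if config.phenotypes is None:
            raise FileNotFoundError("phenofit stage needs a phenotype table [E_INPUT]")
        pheno = pd.read_csv(config.phenotypes)
        traits = [c for c in pheno.columns
                  if c not in ("individual", "population", "year")]
        outputs = {}
        rate_rows = []
        for trait in traits:
            priors = config.trait_priors.get(trait)
            sub = pheno[["population", "year", trait]].rename(columns={trait: "value"})
            if priors is None:
                # weak default priors centred on simple moment estimates
                crab_m = sub.loc[sub["population"] == "crab", "value"].mean()
                wave_m = sub.loc[sub["population"] == "wave", "value"].mean()
                v_hat = sub["value"].var(ddof=1)
                priors = {"p": (0.0, abs(wave_m - crab_m) / 2 + 1e-6),
                          "v_g": (v_hat / 2, v_hat / 2)}
            try:
                fit = phe.fit_stabilizing_selection(
                    sub, trait,
                    p_prior=tuple(priors["p"]), v_g_prior=tuple(priors["v_g"]),
                    f=config.fix_f or 2.0,
                    iters=config.mcmc_iters, burnin=config.mcmc_burnin,
                    seed=config.seed,
                )
            except RuntimeError as exc:
                outputs[trait] = {"error": str(exc)}
                continue
            fpath = out / f"phenofit_{trait}.json"
            _write_json(
                {"point": fit.point, "interval": fit.interval,
                 "rhat": fit.rhat, "f": fit.f},
                fpath,
            )
            outputs[trait] = {"fit": str(fpath),
                              "ratio_median": fit.ratio_median}
            sk = sub[sub["population"] == "skerry"]
            if sk["year"].nunique() >= 2:
                first, last = sk["year"].min(), sk["year"].max()
                start = sk.loc[sk["year"] == first, "value"]
                end = sk.loc[sk["year"] == last, "value"]
                pooled_sd = float(pd.concat([start, end]).std(ddof=1))
                n_gen = max(int(round((last - first) * (config.fix_f or 2.0))), 1)
                rec = phe.evolutionary_rates(
                    float(start.mean()), float(end.mean()), pooled_sd, n_gen,
                    trait=trait,
                )
                rate_rows.append(asdict(rec))
        if rate_rows:
            pd.DataFrame(rate_rows).to_csv(out / "rates.tsv", sep="\t", index=False)
        record("phenofit", outputs)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_json(manifest, out / "manifest.json")
    return manifest
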