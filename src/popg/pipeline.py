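"""Stage orchestration: simulate -> filter -> diversity -> structure ->
demography -> gea, driven by a YAML/dict config.

Every stage writes plain TSV/JSON artifacts into the output directory and
appends to a run log (versions, seeds, site counts at each filter step).
Stages are independently toggleable; an enabled stage with missing inputs
fails before any work is done.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

import popg
from popg import vcfio
from popg.admixture import admixture_nmf, select_k
from popg.artifacts import ArtifactConfig, apply_sequencing_artifacts
from popg.coalescent import SimulationConfig, simulate_coalescent_dataset
from popg.demography import build_folded_joint_sfs, compare_scenarios
from popg.diversity import (
    sample_het_fis,
    summarize_windows,
    windowed_dxy_fst,
    windowed_pi,
    windowed_theta_tajd,
)
from popg.environment import EnvironmentConfig, simulate_environment
from popg.filtering import FilterConfig, filter_variants
from popg.gea import (
    GEAConfig,
    collinearity_filter,
    marginal_permutation_test,
    rda_fit,
    rda_outliers,
)
from popg.ld import ld_decay, ld_prune
from popg.roh import ROHParams, roh_table
from popg.structure import (
    allele_sharing_distance,
    haversine_matrix,
    ibs_distance,
    mrm,
    nj_tree,
    pca,
)
from popg.variants import to_genotype_matrix

__all__ = ["run_pipeline", "PipelineError", "ALL_STAGES"]

ALL_STAGES = ("simulate", "filter", "diversity", "structure", "demography", "gea")


class PipelineError(RuntimeError):
    pass


def _dataclass_from(cfg_cls, block: dict | None):
    block = dict(block or {})
    return cfg_cls(**block)


def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute the configured stages; return a dict of result payloads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    if seed is None:
        seed = int(config.get("seed", 0))

    log: dict = {
        "popg_version": popg.__version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "seed": seed,
        "stages": stages,
        "site_counts": {},
    }
    results: dict = {}

    # ------------------------------------------------------------ inputs
    inputs = config.get("inputs", {})
    need_vcf = any(
        s in stages for s in ("filter", "diversity", "structure", "demography", "gea")
    )
    if need_vcf and "simulate" not in stages and "vcf" not in inputs:
        raise PipelineError(
            "enabled stages need a VCF: provide inputs.vcf or enable simulate"
        )

    table = popmap = env_df = coords = None

    if "simulate" in stages:
        sim_block = dict(config.get("simulate", {}))
        art_block = sim_block.pop("artifacts", None)
        env_block = sim_block.pop("environment", None)
        sim_block.setdefault("seed", seed)
        sim_cfg = _dataclass_from(SimulationConfig, sim_block)
        table = simulate_coalescent_dataset(sim_cfg)
        if art_block is not None:
            art_block.setdefault("seed", seed + 1)
            table = apply_sequencing_artifacts(
                table, _dataclass_from(ArtifactConfig, art_block)
            )
        pops = [s.split("_")[0] for s in table.samples]
        popmap = pd.DataFrame({"sample": table.samples, "population": pops})
        env_cfg = _dataclass_from(EnvironmentConfig, env_block or {})
        if env_block is not None or "gea" in stages or "structure" in stages:
            if env_cfg.seed == 0:
                env_cfg.seed = seed + 2
            coords, env_df = simulate_environment(table.samples, env_cfg)
            popmap = popmap.merge(coords, on="sample")
        vcfio.write_allsites_vcf(table, out / "simulated.vcf")
        vcfio.write_popmap(popmap, out / "popmap.tsv")
        if env_df is not None:
            env_df.reset_index().to_csv(out / "environment.tsv", sep="\t", index=False)
        log["site_counts"]["simulated"] = table.n_sites
        results["simulate"] = {"n_sites": table.n_sites}

    if table is None and "vcf" in inputs:
        table = vcfio.read_allsites_vcf(inputs["vcf"])
        log["site_counts"]["input"] = table.n_sites
    if popmap is None and "popmap" in inputs:
        popmap = vcfio.read_popmap(inputs["popmap"])
    if env_df is None and "env" in inputs:
        env_df = vcfio.read_env_table(inputs["env"])

    def _pops() -> dict[str, list[str]]:
        if popmap is None:
            raise PipelineError("stage requires a popmap")
        return {
            p: list(g["sample"]) for p, g in popmap.groupby("population", sort=True)
        }

    # ------------------------------------------------------------- filter
    if "filter" in stages:
        if table is None:
            raise PipelineError("filter stage requires a VCF")
        fcfg = _dataclass_from(FilterConfig, config.get("filter"))
        table, report = filter_variants(table, fcfg)
        with open(out / "filter_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        pd.DataFrame(
            report.depth_thresholds.items(), columns=["sample", "max_dp"]
        ).to_csv(out / "depth_thresholds.tsv", sep="\t", index=False)
        vcfio.write_allsites_vcf(table, out / "filtered.vcf")
        log["site_counts"]["after_filter"] = table.n_sites
        results["filter"] = report.to_dict()

    matrix = to_genotype_matrix(table) if table is not None else None

    # ---------------------------------------------------------- diversity
    if "diversity" in stages:
        if table is None:
            raise PipelineError("diversity stage requires a VCF")
        dcfg = dict(config.get("diversity", {}))
        window = int(dcfg.get("window", 100_000))
        genome_size = int(
            dcfg.get("genome_size", sum(table.contigs.values()))
        )
        pops = _pops() if popmap is not None else {"all": list(table.samples)}
        frames = []
        for name, members in {**pops, "all": list(table.samples)}.items():
            pi = windowed_pi(table, members, window)
            th = windowed_theta_tajd(table, members, window)
            merged = pi.merge(th, on=["contig", "start", "end"], suffixes=("", "_t"))
            merged.insert(0, "population", name)
            frames.append(merged)
        wins = pd.concat(frames, ignore_index=True)
        wins.to_csv(out / "diversity_windows.tsv", sep="\t", index=False)
        summaries = []
        for name, g in wins.groupby("population"):
            s = summarize_windows(g, ["pi", "theta", "tajd"])
            s.insert(0, "population", name)
            summaries.append(s)
        div = results.setdefault("diversity", {})
        if len(pops) >= 2:
            (na, nb) = sorted(pops)[:2]
            dx = windowed_dxy_fst(table, pops[na], pops[nb], window)
            dx.to_csv(out / "divergence_windows.tsv", sep="\t", index=False)
            s = summarize_windows(dx, ["dxy", "fst"])
            s.insert(0, "population", f"{na}~{nb}")
            summaries.append(s)
            div["fst_windows"] = len(dx)
        pd.concat(summaries, ignore_index=True).to_csv(
            out / "diversity_summary.tsv", sep="\t", index=False
        )
        hf = sample_het_fis(matrix)
        hf.to_csv(out / "het_fis.tsv", sep="\t", index=False)
        roh_cfg = _dataclass_from(ROHParams, dcfg.get("roh"))
        intervals, fr = roh_table(matrix, genome_size, roh_cfg)
        intervals.to_csv(out / "roh_intervals.tsv", sep="\t", index=False)
        fr.to_csv(out / "froh.tsv", sep="\t", index=False)
        if matrix.n_sites >= 2:
            ld = ld_decay(
                matrix,
                max_dist=int(dcfg.get("ld_max_dist", 10_000)),
                bin_size=int(dcfg.get("ld_bin", 5_000)),
            )
            ld.to_csv(out / "ld_decay.tsv", sep="\t", index=False)
        div["n_windows"] = len(wins)

    # ---------------------------------------------------------- structure
    if "structure" in stages:
        if matrix is None:
            raise PipelineError("structure stage requires a VCF")
        scfg = dict(config.get("structure", {}))
        if bool(scfg.get("ld_prune", True)) and matrix.n_sites > 1:
            retained = ld_prune(matrix)
            pruned = _subset_matrix(matrix, retained)
        else:
            pruned = matrix
        pres = pca(pruned, max_missing=float(scfg.get("pca_max_missing", 0.01)))
        pd.DataFrame(
            pres.scores,
            columns=[f"PC{i + 1}" for i in range(pres.scores.shape[1])],
        ).assign(sample=pres.samples).to_csv(
            out / "pca_scores.tsv", sep="\t", index=False
        )
        ibs = ibs_distance(matrix)
        pd.DataFrame(ibs.values, index=ibs.samples, columns=ibs.samples).to_csv(
            out / "ibs_distance.tsv", sep="\t"
        )
        asd = allele_sharing_distance(table)
        (out / "nj_tree.nwk").write_text(nj_tree(asd) + "\n")
        st = results.setdefault("structure", {})
        st["pca_explained"] = [float(v) for v in pres.explained[:4]]

        if popmap is not None and {"lat", "lon"}.issubset(popmap.columns):
            coords_df = popmap[["sample", "lat", "lon"]]
            geo = haversine_matrix(coords_df)
            geo = _align_distance(geo, ibs.samples)
            mres = mrm(
                ibs, geo,
                n_perm=int(scfg.get("mrm_permutations", 999)),
                seed=seed + 10,
            )
            with open(out / "mrm.json", "w") as fh:
                json.dump(mres.__dict__, fh, indent=2)
            iu = np.triu_indices(len(ibs.samples), k=1)
            pd.DataFrame(
                {"ibs_dist": ibs.values[iu], "km": geo.values[iu]}
            ).to_csv(out / "ibd_scatter.tsv", sep="\t", index=False)
            st["mrm_r2"] = mres.r_squared
            st["mrm_p"] = mres.p_value

        k_range = scfg.get("k_range", [1, 4])
        ks = range(int(k_range[0]), int(k_range[1]) + 1)
        adm = {
            k: admixture_nmf(
                pruned, k,
                n_runs=int(scfg.get("nmf_runs", 10)),
                seed=seed + 20 + k,
            )
            for k in ks
            if k <= pruned.n_samples
        }
        best_k = select_k(adm)
        pd.DataFrame(
            [(k, r.cross_entropy) for k, r in adm.items()],
            columns=["K", "cross_entropy"],
        ).to_csv(out / "k_selection.tsv", sep="\t", index=False)
        for k, r in adm.items():
            pd.DataFrame(
                r.Q, columns=[f"Q{i + 1}" for i in range(k)]
            ).assign(sample=r.samples).to_csv(
                out / f"admixture_K{k}.tsv", sep="\t", index=False
            )
        st["best_k"] = int(best_k)

    # --------------------------------------------------------- demography
    if "demography" in stages:
        if table is None:
            raise PipelineError("demography stage requires a VCF")
        pops = _pops()
        if len(pops) < 2:
            raise PipelineError("demography stage needs two populations")
        dcfg = dict(config.get("demography", {}))
        (na, nb) = sorted(pops)[:2]
        proj = dcfg.get("projection")
        sfs = build_folded_joint_sfs(
            table, pops[na], pops[nb],
            projection=tuple(proj) if proj else None,
            keep_fraction=float(dcfg.get("keep_fraction", 0.9)),
        )
        np.savetxt(
            out / "joint_sfs.tsv", sfs.counts, delimiter="\t",
            header=f"projection {sfs.n1} {sfs.n2}; pops {na} {nb}",
        )
        fits = compare_scenarios(
            sfs,
            mu=float(dcfg.get("mu", 1e-8)),
            n_cycles=int(dcfg.get("n_cycles", 15)),
            n_sims=int(dcfg.get("n_sims", 20_000)),
            seed=seed + 30,
        )
        rows = []
        for f in fits:
            payload = {
                **f.params_dict(),
                "MaxEstLhood": f.max_est_lhood,
                "k": f.k,
                "AIC": f.aic,
                "dAIC": f.delta_aic,
            }
            with open(out / f"fit_{f.model.scenario}.json", "w") as fh:
                json.dump(payload, fh, indent=2)
            rows.append(payload)
        pd.DataFrame(rows).to_csv(out / "demography_comparison.tsv", sep="\t", index=False)
        results["demography"] = {
            "best": min(fits, key=lambda f: f.aic).model.scenario
        }

    # ---------------------------------------------------------------- gea
    if "gea" in stages:
        if matrix is None or env_df is None:
            raise PipelineError("gea stage requires a VCF and environment table")
        gcfg = _dataclass_from(GEAConfig, config.get("gea"))
        env = env_df.loc[matrix.samples]
        retained = collinearity_filter(env, gcfg.spearman_threshold)
        env_r = env[retained]
        rres = rda_fit(matrix, env_r, gcfg)
        outl = rda_outliers(rres, axes=gcfg.axes, sd=gcfg.outlier_sd)
        outl.to_csv(out / "rda_outliers.tsv", sep="\t", index=False)
        pd.DataFrame(
            rres.scores,
            columns=[f"RDA{i + 1}" for i in range(rres.scores.shape[1])],
        ).assign(sample=rres.samples).to_csv(
            out / "rda_scores.tsv", sep="\t", index=False
        )
        pvals = {
            v: marginal_permutation_test(
                matrix, env_r, v, n_perm=gcfg.n_perm, seed=seed + 40
            )
            for v in retained
        }
        pd.DataFrame(pvals.items(), columns=["variable", "p_value"]).to_csv(
            out / "env_pvalues.tsv", sep="\t", index=False
        )
        results["gea"] = {
            "retained_env": retained,
            "n_outliers": int(outl["snp_index"].nunique()) if len(outl) else 0,
        }

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return results


def _subset_matrix(matrix, idx):
    from popg.variants import GenotypeMatrix

    return GenotypeMatrix(
        samples=list(matrix.samples),
        dosage=matrix.dosage[:, idx],
        contig=None if matrix.contig is None else matrix.contig[idx],
        pos=None if matrix.pos is None else matrix.pos[idx],
    )


def _align_distance(dm, samples):
    from popg.structure import DistanceMatrix

    order = [dm.samples.index(s) for s in samples]
    return DistanceMatrix(list(samples), dm.values[np.ix_(order, order)])
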