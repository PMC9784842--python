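"""End-to-end pipeline: simulate -> QC -> blocks -> stats -> GWAS -> QTL
-> prediction, with YAML configuration and a JSON run manifest.

Every stage is callable on in-memory objects; :func:`run_pipeline`
chains them and writes TSV outputs plus a manifest recording the seed,
thresholds and an MD5 per output file (identical seeds give
byte-identical bundles).
"""

from __future__ import annotations

import hashlib
import json
import os
import zlib
from contextlib import contextmanager
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .gwas import HaplotypeGWAS
from .haplo import (build_haploblocks, build_marker_matrix, call_haplotypes,
                    filter_haplotypes, marker_r2)
from .phenostats import (SCOPES, descriptives, heritability, lsmeans,
                         pearson_correlations, similarity_pca,
                         variance_components)
from .qc import filter_snps, impute_mni, recode_reference
from .qtl import (classify_scopes, merge_mtas, pleiotropy_scan, predict_yield,
                  qtl_table, transgression_report)
from .simulate import (PlantedQTL, RILPopulation, TraitArchitecture,
                       funnel_cross, inject_missingness, plant_phenotypes,
                       simulate_founders)

DEFAULT_CONFIG = {
    "sim": {
        "n_snps": 2000,
        "n_lines": 400,
        "selfing_gens": 4,
        "diversity": 0.59,
        "missing_rate": 0.01,
        "traits": {
            "YLD": {
                "V_G": 1.0, "V_GE": 0.5, "V_GT": 0.25, "V_R": 1.0,
                "e": 7, "t": 2, "mean": 75.0, "treatment_shift": 5.0,
                "n_qtl": 3, "qtl_effect": 1.0,
            },
        },
    },
    "qc": {"max_missing": 0.05, "min_maf": 0.05},
    "blocks": {"max_pair_bp": 500_000, "fourth_gamete_max": 0.01,
               "dprime_required": 1.0, "maf_min": 0.05},
    "gwas": {"n_reps": 100, "train_frac": 0.8, "alpha": 0.05,
             "inclusion_min": 2, "scopes": ["N0", "N1", "across"]},
    "qtl": {"r2_min": 0.8, "cm_window": 5.0},
    "predict": {"trait": "YLD"},
}


def load_config(path: str | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, vals in user.items():
            if isinstance(vals, dict):
                cfg.setdefault(section, {}).update(vals)
            else:
                cfg[section] = vals
    return cfg


def _architectures(sim_cfg: dict, n_snps: int, rng: np.random.Generator,
                   markers) -> list[TraitArchitecture]:
    archs = []
    for trait, tc in sim_cfg["traits"].items():
        tc = dict(tc)
        n_qtl = tc.pop("n_qtl", 0)
        effect = tc.pop("qtl_effect", 1.0)
        qtl_list = []
        if n_qtl:
            pos = np.linspace(0, n_snps - 1, n_qtl + 2)[1:-1].astype(int)
            for p in pos:
                carriers = rng.choice(8, size=rng.integers(1, 4), replace=False)
                eff = np.zeros(8)
                eff[carriers] = effect
                qtl_list.append(PlantedQTL(markers[p], eff))
        archs.append(TraitArchitecture(trait=trait, qtl=qtl_list, **tc))
    return archs


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage '{name}' failed: {e}") from e


def run_pipeline(config: dict | str | None = None, seed: int = 0,
                 out_dir: str | None = None) -> dict:
    """Run the full analysis on a fresh simulation; returns the bundle
    (objects + tables) and, when ``out_dir`` is given, writes TSVs and a
    manifest.json.  A stage failure aborts with a stage-tagged error;
    outputs of completed stages are still written."""
    cfg = load_config(config) if isinstance(config, (str, type(None))) \
        else config
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    bundle: dict = {"config": cfg, "seed": seed}
    try:
        _run_stages(cfg, seeds, bundle)
    except PipelineError:
        if out_dir:
            try:
                _write_bundle(bundle, out_dir)
            except Exception:
                pass
        raise
    if out_dir:
        _write_bundle(bundle, out_dir)
    return bundle


def _run_stages(cfg: dict, seeds: list[int], bundle: dict) -> None:
    with _stage("simulate"):
        sim = cfg["sim"]
        panel = simulate_founders(sim["n_snps"], None, sim["diversity"],
                                  seeds[0])
        pop = funnel_cross(panel, sim["n_lines"], sim["selfing_gens"], seeds[1])
        rng = np.random.default_rng(seeds[2])
        archs = _architectures(sim, sim["n_snps"], rng,
                               list(panel.map.markers))
        phenos = [plant_phenotypes(pop, a, seeds[3] + k)
                  for k, a in enumerate(archs)]
        pheno = pd.concat(phenos, ignore_index=True)
        if sim.get("missing_rate", 0) > 0:
            pop_obs = inject_missingness(pop, sim["missing_rate"], seeds[4])
        else:
            pop_obs = pop
        bundle.update(panel=panel, population=pop_obs, phenotypes=pheno,
                      architectures=archs)

    with _stage("qc"):
        keep, stats = filter_snps(pop_obs, panel, cfg["qc"]["max_missing"],
                                  cfg["qc"]["min_maf"])
        sub_map = type(panel.map)(panel.map.table.iloc[keep])
        panel_q = type(panel)(panel.founder_names, panel.gametes[:, keep],
                              sub_map)
        pop_q = RILPopulation(list(pop_obs.line_names),
                              pop_obs.genotypes[:, keep], sub_map,
                              None if pop_obs.mosaic is None
                              else pop_obs.mosaic[:, keep, :],
                              pop_obs.selfing_gens)
        reference = cfg["qc"].get("reference", panel_q.founder_names[-1])
        numeric = impute_mni(recode_reference(pop_q, panel_q, reference))
        bundle.update(snp_stats=stats.table, retained=keep, numeric=numeric)

    with _stage("blocks"):
        b = cfg["blocks"]
        blocks, singular = build_haploblocks(panel_q, b["max_pair_bp"],
                                             b["fourth_gamete_max"],
                                             b["dprime_required"],
                                             b["maf_min"])
        hts, assignments = call_haplotypes(blocks, pop_q, panel_q)
        retained_hts = filter_haplotypes(hts)
        matrix = build_marker_matrix(retained_hts, singular, pop_q, panel_q,
                                     assignments, blocks)
        bundle.update(blocks=blocks, haplotypes=hts,
                      retained_haplotypes=retained_hts, marker_matrix=matrix)

    with _stage("stats"):
        traits = list(sim["traits"])
        lsm = {s: pd.DataFrame({t: lsmeans(pheno, t, s) for t in traits})
               for s in SCOPES}
        desc_rows = []
        herit_rows = []
        for t in traits:
            for s in SCOPES:
                d = descriptives(lsm[s][t])
                d.update(trait=t, scope=s)
                desc_rows.append(d)
            vc = variance_components(pheno, t, model="line")
            herit_rows.append({"trait": t, "h2": heritability(vc, "line"),
                               **vc.as_dict(), "e": vc.e, "t": vc.t})
        corr_r, corr_p = (pearson_correlations(lsm["across"])
                          if len(traits) > 1 else (None, None))
        sim_mat, coords, var_exp = similarity_pca(
            np.vstack([pop_q.genotypes, panel_q.genotypes()]))
        bundle.update(lsmeans=lsm, descriptives=pd.DataFrame(desc_rows),
                      heritability=pd.DataFrame(herit_rows),
                      correlations=(corr_r, corr_p),
                      pca=(coords, var_exp), similarity=sim_mat)

    with _stage("gwas"):
        g = cfg["gwas"]
        results = {}
        mta_frames = []
        for t in traits:
            for s in g["scopes"]:
                res = HaplotypeGWAS(lsm[s][t], matrix, trait=t, scope=s).fit(
                    n_reps=g["n_reps"], train_frac=g["train_frac"],
                    seed=seeds[5] + zlib.crc32(f"{t}:{s}".encode()) % 10_000,
                    alpha=g["alpha"])
                results[(t, s)] = res
                mta_frames.append(res.mta)
        mta_all = pd.concat(mta_frames)
        sig = mta_all[mta_all["significant"]].copy()
        meta = matrix.meta
        sig["chrom"] = meta.loc[sig.index, "chrom"].to_numpy()
        sig["cM"] = meta.loc[sig.index, "cM"].to_numpy()
        bundle.update(gwas=results, mta=mta_all, significant_mta=sig)

    with _stage("qtl"):
        qc_cfg = cfg["qtl"]
        ld = marker_r2(matrix) if matrix.n_markers <= 4000 else None
        qtls = merge_mtas(sig, ld, qc_cfg["r2_min"], qc_cfg["cm_window"])
        accounting = classify_scopes(qtls, sig)
        pleio = pleiotropy_scan(qtls, qc_cfg["cm_window"])
        bundle.update(qtls=qtls, accounting=accounting, pleiotropy=pleio)

    with _stage("predict"):
        pt = cfg["predict"]["trait"]
        if pt in traits:
            y = lsm["across"][pt]
            sig_t = sig[sig["trait"] == pt]
            qtl_cols = matrix.values[list(dict.fromkeys(sig_t.index))] \
                if len(sig_t) else matrix.values.iloc[:, :0]
            comp = lsm["across"][[t for t in traits if t != pt]] \
                if len(traits) > 1 else None
            bundle["prediction"] = predict_yield(y, qtl_cols, comp, "across")


def _hash_file(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def _write_bundle(bundle: dict, out_dir: str) -> None:
    """Write whatever stages completed; missing keys are skipped so a
    failed run retains its partial outputs."""
    mio.ensure_dir(out_dir)
    p = lambda name: os.path.join(out_dir, name)
    if "panel" in bundle:
        mio.write_map(bundle["panel"].map, p("map.tsv"))
        mio.write_founders(bundle["panel"], p("founders.tsv"))
    if "population" in bundle:
        mio.write_genotypes(bundle["population"], p("genotypes.tsv"))
    if "phenotypes" in bundle:
        mio.write_phenotypes(bundle["phenotypes"], p("phenotypes.tsv"))
    if "snp_stats" in bundle:
        bundle["snp_stats"].to_csv(p("snp_report.tsv"), sep="\t",
                                   float_format="%.6f")
    if "numeric" in bundle:
        bundle["numeric"].to_frame().to_csv(p("numeric_matrix.tsv"), sep="\t",
                                            float_format="%.4f")
    if "blocks" in bundle:
        pd.DataFrame([{
            "block": b.id, "chrom": b.chrom, "start_bp": b.bp_span[0],
            "end_bp": b.bp_span[1], "start_cM": b.cm_span[0],
            "end_cM": b.cm_span[1], "n_snps": len(b.members),
        } for b in bundle["blocks"]]).to_csv(p("blocks.tsv"), sep="\t",
                                             index=False,
                                             float_format="%.6f")
    if "haplotypes" in bundle:
        pd.DataFrame([{
            "block": h.block_id, "alleles": h.alleles,
            "frequency": h.frequency,
            "founders": "".join("1" if f else "0"
                                for f in h.founder_membership),
        } for h in bundle["haplotypes"]]).to_csv(
            p("haplotypes.tsv"), sep="\t", index=False, float_format="%.6f")
    if "marker_matrix" in bundle:
        mio.write_marker_matrix(bundle["marker_matrix"],
                                p("marker_matrix.tsv"), p("marker_meta.tsv"))
    if "descriptives" in bundle:
        bundle["descriptives"].to_csv(p("descriptives.tsv"), sep="\t",
                                      index=False, float_format="%.4f")
        bundle["heritability"].to_csv(p("heritability.tsv"), sep="\t",
                                      index=False, float_format="%.6f")
        if bundle["correlations"][0] is not None:
            bundle["correlations"][0].to_csv(p("correlations.tsv"), sep="\t",
                                             float_format="%.4f")
    if "mta" in bundle:
        bundle["mta"].to_csv(p("mta.tsv"), sep="\t", float_format="%.6g")
        man = pd.concat([r.manhattan_frame()
                         for r in bundle["gwas"].values()])
        man.to_csv(p("manhattan.tsv"), sep="\t", float_format="%.6f")
    if "qtls" in bundle:
        qtl_table(bundle["qtls"]).to_csv(p("qtl.tsv"), sep="\t", index=False,
                                         float_format="%.6g")
        bundle["accounting"].to_csv(p("qtl_accounting.tsv"), sep="\t",
                                    float_format="%.1f")
        pd.DataFrame([asdict(x) for x in bundle["pleiotropy"]]).to_csv(
            p("pleiotropy.tsv"), sep="\t", index=False, float_format="%.4f")
    if bundle.get("prediction") is not None:
        pred = bundle["prediction"]
        with open(p("prediction.txt"), "w") as fh:
            fh.write(pred.summary() + "\n")
        if pred.fitted is not None:
            pred.fitted.to_csv(p("prediction_fit.tsv"), sep="\t",
                               float_format="%.6f")
    files = sorted(f for f in os.listdir(out_dir)
                   if f.endswith((".tsv", ".txt")))
    manifest = {
        "seed": bundle["seed"],
        "config": bundle["config"],
        "outputs": {f: _hash_file(os.path.join(out_dir, f)) for f in files},
    }
    with open(p("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
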