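"""End-to-end analysis pipeline driven by one YAML configuration.

Stages: load (or simulate) genotypes -> drop monomorphic loci ->
diversity/HWE table -> clustering (K selection, consensus fit, migrant
calls) -> spatial PCA with permutation tests -> sex-stratified IBD ->
individual inbreeding (plus optional estimator evaluation) -> LD-Ne per
cluster -> travelling-window scan.  Every stage writes its own TSV into
the output directory; a JSON manifest records seeds, versions and
timings.  All randomness derives from the single top-level seed, so a
rerun with the same configuration reproduces every numeric output.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import classify_migrants, fit_admixture_replicated, select_k
from .diversity import diversity_table
from .hwds import hwds_profile, profile_table
from .inbreeding import estimate_all, evaluate_estimators
from .io import read_genotypes, write_genotypes
from .kinship import ibd_analysis, loiselle_kinship
from .matrix import SampleMetadata, allele_frequencies, filter_monomorphic
from .ne import ld_ne
from .simulate import SimulationConfig, simulate_structured_pop
from .spca import delaunay_connectivity, global_local_tests, spca


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage. Partial outputs remain."""


DEFAULTS: dict = {
    "seed": 1,
    "filters": {"drop_monomorphic": True},
    "clustering": {"k_min": 1, "k_max": 4, "n_replicates": 5,
                   "burn_in": 300, "reps": 1500, "q_threshold": 0.8},
    "spca": {"n_permutations": 10_000},
    "ibd": {"n_permutations": 20_000, "classes": [25, 50, 100, 200, 400, 800]},
    "inbreeding": {"estimator": "ml", "evaluate": False, "n_per_level": 100},
    "ne": {"freq_cutoff": 0.02},
    "hwds": {"window_size": 30, "step": 1, "hwe_mc_reps": 20_000,
             "axis": [[39.2, 23.9], [36.2, 27.2]], "designated_cluster": None},
}


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: dict, output_dir=None) -> dict:
    """Run every configured stage; returns a dict of result tables.

    ``cfg`` is a configuration dict (see :data:`DEFAULTS` and
    :func:`load_config`); ``output_dir`` overrides ``cfg['output_dir']``.
    """
    out = Path(output_dir or cfg.get("output_dir", "popgen_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 1))
    manifest: dict = {"version": __version__, "seed": seed, "stages": {}}
    results: dict = {}
    stage = "load"
    t0 = time.time()

    def done(name: str) -> None:
        nonlocal t0
        manifest["stages"][name] = round(time.time() - t0, 3)
        t0 = time.time()

    try:
        inp = cfg.get("input", {})
        if inp.get("genotypes"):
            gm, meta = read_genotypes(inp["genotypes"], inp.get("format", "csv"))
            if meta is None and inp.get("metadata"):
                mdf = pd.read_csv(inp["metadata"], dtype={"sample_id": str}).set_index("sample_id")
                meta = SampleMetadata(mdf)
            if meta is None:
                raise PipelineError("load: metadata (coordinates, sex, region) required")
        else:
            sim = dict(inp.get("simulate", {}))
            sim.setdefault("seed", seed)
            gm, meta = simulate_structured_pop(SimulationConfig(**sim))
        done(stage)

        stage = "filter"
        if cfg["filters"].get("drop_monomorphic", True):
            gm = filter_monomorphic(gm)
        write_genotypes(gm, out / "genotypes.csv", "csv", meta)
        done(stage)

        stage = "diversity"
        regions = meta.table.loc[gm.sample_ids, "region"].astype(str)
        assignments = {r: list(ids) for r, ids in regions.groupby(regions).groups.items()}
        assignments["all"] = list(gm.sample_ids)
        div = diversity_table(gm, assignments, seed=seed, mc_reps=20_000,
                              max_enum_tables=20_000)
        _write(div, out / "diversity.tsv")
        results["diversity"] = div
        done(stage)

        stage = "clustering"
        cc = cfg["clustering"]
        k_range = range(int(cc["k_min"]), int(cc["k_max"]) + 1)
        k_star, k_table = select_k(gm, k_range, n_replicates=int(cc["n_replicates"]),
                                   seed=seed, burn_in=int(cc["burn_in"]),
                                   reps=int(cc["reps"]))
        model, _ = fit_admixture_replicated(gm, k_star, n_replicates=int(cc["n_replicates"]),
                                            seed=seed + 7, burn_in=int(cc["burn_in"]),
                                            reps=int(cc["reps"]))
        q_df = pd.DataFrame(model.q, index=model.sample_ids,
                            columns=[f"q{k + 1}" for k in range(k_star)])
        q_df.insert(0, "sample_id", q_df.index)
        _write(k_table, out / "k_selection.tsv")
        _write(q_df, out / "q_matrix.tsv")
        migrants = pd.DataFrame([m.__dict__ for m in classify_migrants(
            model, meta, q_threshold=float(cc["q_threshold"]))])
        _write(migrants, out / "migrants.tsv")
        results.update(k_star=k_star, k_table=k_table, cluster_model=model,
                       migrants=migrants)
        done(stage)

        stage = "spca"
        coords = meta.coords(gm.sample_ids)
        W, edges = delaunay_connectivity(coords)
        res = spca(gm, W)
        gp, lp = global_local_tests(gm, W, n_perm=int(cfg["spca"]["n_permutations"]),
                                    seed=seed + 11)
        eig_df = pd.DataFrame({"component": np.arange(1, len(res.eigenvalues) + 1),
                               "eigenvalue": res.eigenvalues})
        _write(eig_df, out / "spca_eigenvalues.tsv")
        scores = pd.DataFrame(res.scores[:, :3], index=gm.sample_ids,
                              columns=["score1", "score2", "score3"])
        scores.insert(0, "sample_id", scores.index)
        scores["latitude"] = coords[:, 0]
        scores["longitude"] = coords[:, 1]
        _write(scores, out / "spca_scores.tsv")
        (out / "spca_tests.tsv").write_text(f"global_p\tlocal_p\n{gp:.6g}\t{lp:.6g}\n")
        results.update(spca=res, spca_global_p=gp, spca_local_p=lp)
        done(stage)

        stage = "ibd"
        kin = loiselle_kinship(gm)
        ibd_tables = []
        for sex in ("female", "male"):
            ids = [s for s in gm.sample_ids
                   if meta.table.loc[s, "sex"] == sex
                   and meta.table.loc[s, "age_class"] == "adult"]
            if len(ids) < 5:
                continue
            r = ibd_analysis(kin, meta.coords(ids), cfg["ibd"]["classes"],
                             subset=ids, n_perm=int(cfg["ibd"]["n_permutations"]),
                             seed=seed + 13)
            t = r.table.copy()
            t.insert(0, "subset", f"adult_{sex}s")
            t["population_mean"] = r.population_mean
            ibd_tables.append(t)
        if ibd_tables:
            ibd_df = pd.concat(ibd_tables, ignore_index=True)
            _write(ibd_df, out / "ibd.tsv")
            results["ibd"] = ibd_df
        done(stage)

        stage = "inbreeding"
        freqs = allele_frequencies(gm)
        f_hat = estimate_all(gm, freqs, cfg["inbreeding"].get("estimator", "ml"))
        f_df = f_hat.reset_index()
        _write(f_df, out / "inbreeding.tsv")
        results["inbreeding"] = f_hat
        if cfg["inbreeding"].get("evaluate", False):
            ev = evaluate_estimators(freqs, n_per_level=int(cfg["inbreeding"]["n_per_level"]),
                                     seed=seed + 17)
            _write(ev, out / "estimator_evaluation.tsv")
            results["estimator_evaluation"] = ev
        done(stage)

        stage = "ne"
        ne_rows = []
        for label, ids in assignments.items():
            if len(ids) < 10:
                continue
            try:
                est = ld_ne(gm, ids, freq_cutoff=float(cfg["ne"]["freq_cutoff"]))
            except ValueError:
                continue
            ne_rows.append({"subset": label, "n": len(ids), "ne": est.ne,
                            "ci_low": est.ci_low, "ci_high": est.ci_high,
                            "mean_r2": est.mean_r2, "expected_r2": est.expected_r2,
                            "s_harmonic": est.s_harmonic,
                            "n_comparisons": est.n_comparisons})
        ne_df = pd.DataFrame(ne_rows)
        _write(ne_df, out / "ne.tsv")
        results["ne"] = ne_df
        done(stage)

        stage = "hwds"
        hc = cfg["hwds"]
        axis = hc["axis"]
        designated = hc.get("designated_cluster")
        model = results["cluster_model"]
        if designated is None:
            # cluster dominating the NW end of the axis
            from .hwds import order_along_axis
            ordered, _ = order_along_axis(meta, list(gm.sample_ids),
                                          tuple(axis[0]), tuple(axis[1]))
            head = [model.sample_ids.index(s) for s in ordered[:max(5, len(ordered) // 10)]]
            designated = int(np.argmax(model.q[head].mean(axis=0)))
        if gm.n_samples >= int(hc["window_size"]):
            windows = hwds_profile(
                gm, meta, tuple(axis[0]), tuple(axis[1]),
                cluster_model=model, designated_cluster=designated,
                window_size=int(hc["window_size"]), step=int(hc.get("step", 1)),
                hwe_mc_reps=int(hc["hwe_mc_reps"]),
                ne_cutoff=float(cfg["ne"]["freq_cutoff"]), seed=seed + 19)
            hw_df = profile_table(windows)
            _write(hw_df, out / "hwds.tsv")
            results["hwds"] = hw_df
        done(stage)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    results["manifest"] = manifest
    return results
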