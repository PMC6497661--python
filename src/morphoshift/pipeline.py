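"""End-to-end orchestration: landmarks -> consensus -> morphospace ->
disparity/tanglegram -> shift detection -> model comparison.

A single :class:`PipelineConfig` (loadable from YAML) drives all stages; every
stage writes its outputs and a manifest entry under the output directory.  The
run is deterministic given the config and seeds, so a rerun (or a rerun after
deleting any stage's outputs) reproduces the bundle byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import disparity, landmarks as lm, models, morphospace as ms, shifts as sh
from . import synthetic, tanglegram as tg
from .trees import PhyloTree, prune_and_match

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str = "morphoshift_out"
    # inputs (either simulate or load)
    landmarks_csv: str | None = None
    curve_spec: str | None = None
    tree_file: str | None = None
    states_csv: str | None = None
    simulate: dict | None = None           # synthetic-fixture parameters
    scope_species: list[str] | None = None  # named subclade (None = full tree)
    # analysis settings
    correction: str = "both"               # ppca | pca | both
    score_scale: float = 100.0
    slide: bool = True
    n_sim_dtt: int = 1000
    n_sim_tangle: int = 1000
    max_shifts: int | None = None          # default: 50 full tree, 20 subclade
    criterion: str = "pbic"
    n_bootstrap: int = 0
    n_parallel_perm: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)
    path.write_text(json.dumps(obj, indent=1, default=default))


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        simp = dict(config.simulate)
        n_species = int(simp.pop("n_species", 64))
        tree = synthetic.simulate_tree(n_species, seed=config.seed)
        dataset = synthetic.simulate_landmark_dataset(
            tree, seed=config.seed + 1, **simp)
        tree.write(outdir / "tree.nwk")
        lm.write_landmarks(dataset, outdir / "landmarks.csv")
        lm.write_curve_spec(dataset, outdir / "curves.json")
        states = None
    else:
        tree = PhyloTree.from_file(config.tree_file)
        dataset = lm.read_landmarks(config.landmarks_csv, "csv",
                                    curve_spec_path=config.curve_spec)
        states = None
        if config.states_csv:
            states = pd.read_csv(config.states_csv)
    return tree, dataset, states


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a dict of in-memory results and writes a bundle."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    results: dict = {}

    tree, dataset, states = _load_inputs(config, outdir)

    # stage: prune/match tree to species present in the data
    species_present = sorted(set(dataset.species.values()))
    tree, match_report = prune_and_match(tree, species_present)
    if config.scope_species:
        tree, sub_report = prune_and_match(tree, config.scope_species)
        match_report["subclade"] = sub_report
        keep = set(tree.tip_labels)
        keep_idx = [i for i, sid in enumerate(dataset.specimen_ids)
                    if dataset.species[sid] in keep]
        dataset = dataset.copy()
        dataset.coordinates = dataset.coordinates[keep_idx]
        dataset.missing = dataset.missing[keep_idx]
        dataset.specimen_ids = [dataset.specimen_ids[i] for i in keep_idx]
    _write_json(outdir / "tree_match.json", match_report)
    manifest["stages"]["tree_match"] = {"n_tips": tree.n_tips}
    max_shifts = config.max_shifts
    if max_shifts is None:
        max_shifts = 20 if config.scope_species else 50
    results["tree"] = tree
    results["max_shifts"] = max_shifts

    # stage: completion + superimposition + species consensus
    if dataset.missing.any():
        dataset = lm.estimate_missing(dataset)
    alignment = lm.gpa_align(dataset, slide=config.slide and bool(dataset.curves))
    names, consensus = lm.species_consensus(
        alignment, dataset.species, dataset.bilateral_pairs, dataset.midline)
    name_pos = {n: i for i, n in enumerate(names)}
    consensus = consensus[[name_pos[l] for l in tree.tip_labels]]
    _write_json(outdir / "gpa.json", {
        "iterations": alignment.iterations, "converged": alignment.converged,
        "n_species": len(names)})
    flat = consensus.reshape(tree.n_tips, -1)
    pd.DataFrame(flat, index=tree.tip_labels).to_csv(outdir / "consensus_shapes.csv")

    # stage: morphospaces
    spaces = {}
    modes = {"ppca": ["phylogenetic"], "pca": ["none"],
             "both": ["phylogenetic", "none"]}[config.correction]
    for mode in modes:
        space = (ms.ppca(flat, tree) if mode == "phylogenetic" else
                 ms.pca(flat, species=tree.tip_labels))
        space.n_critical = ms.parallel_analysis(
            flat, tree if mode == "phylogenetic" else None,
            n_perm=max(100, config.n_parallel_perm), seed=config.seed + 2)
        ncrit = max(space.n_critical, 1)
        space.r2 = ms.axis_variance_r2(flat, space.scores[:, :ncrit])
        spaces[mode] = space
        tag = "ppca" if mode == "phylogenetic" else "pca"
        pd.DataFrame(space.scores[:, :ncrit], index=tree.tip_labels).to_csv(
            outdir / f"scores_{tag}.csv")
        _write_json(outdir / f"morphospace_{tag}.json", {
            "eigenvalues": space.eigenvalues[:10], "n_critical": space.n_critical,
            "r2": space.r2, "r2_total": float(space.r2.sum())})
    results["morphospaces"] = spaces

    # stage: disparity through time
    dtt = disparity.mdi_test(tree, consensus, n_sim=config.n_sim_dtt,
                             seed=config.seed + 3)
    pd.DataFrame({"time": dtt.times, "observed": dtt.observed,
                  "median_sim": dtt.median_curve,
                  "lo95": dtt.envelope[0], "hi95": dtt.envelope[1]}).to_csv(
        outdir / "dtt_curve.csv", index=False)
    _write_json(outdir / "dtt.json", {"mdi": dtt.mdi, "p_value": dtt.p_value,
                                      "n_sim": dtt.n_sim})
    results["dtt"] = dtt

    # stage: tanglegram
    tangle = tg.displacement_null_test(tree, consensus,
                                       n_sim=config.n_sim_tangle,
                                       seed=config.seed + 4)
    _write_json(outdir / "tanglegram.json", {
        "tip_displacement": tangle.tip_displacement, "p_value": tangle.p_value,
        "null_range": [float(tangle.null_tds.min()), float(tangle.null_tds.max())],
        "n_sim": tangle.n_sim})
    results["tanglegram"] = tangle

    # stage: shift detection per morphospace
    shift_results = {}
    for mode, space in spaces.items():
        tag = "ppca" if mode == "phylogenetic" else "pca"
        ncrit = max(space.n_critical, 1)
        scores = ms.scale_scores(space.scores[:, :ncrit], config.score_scale)
        settings = sh.SearchSettings(max_shifts=max_shifts,
                                     criterion=config.criterion,
                                     seed=config.seed + 5)
        cfg = sh.detect_shifts(tree, scores, settings)
        if config.n_bootstrap >= 20 and cfg.n_shifts:
            sh.bootstrap_support(tree, scores, cfg, config.n_bootstrap,
                                 seed=config.seed + 6, settings=settings)
        rows = []
        for i, b in enumerate(cfg.shift_branches):
            tips_under = [tree.tip_labels[r]
                          for r in np.where(tree.tip_masks[b])[0]]
            rows.append({"branch": b, "n_tips": len(tips_under),
                         "tip_set": ";".join(sorted(tips_under)[:4]),
                         "support": cfg.support.get(b, np.nan),
                         **{f"beta_{j + 1}": cfg.beta[i, j]
                            for j in range(cfg.beta.shape[1])}})
        pd.DataFrame(rows).to_csv(outdir / f"shifts_{tag}.csv", index=False)
        _write_json(outdir / f"shifts_{tag}.json", {
            "n_shifts": cfg.n_shifts, "branches": cfg.shift_branches,
            "score": cfg.score, "loglik": cfg.loglik,
            "criterion": cfg.criterion, "support": cfg.support})
        shift_results[tag] = cfg
    results["shifts"] = shift_results

    # stage: model comparison on the primary morphospace
    space = spaces.get("phylogenetic", next(iter(spaces.values())))
    tag = "ppca" if "phylogenetic" in spaces else "pca"
    ncrit = max(space.n_critical, 1)
    scores = ms.scale_scores(space.scores[:, :ncrit], config.score_scale)
    fits: dict = {
        "BM": models.fit_bm(tree, scores),
        "OU1": models.fit_ou1(tree, scores),
        "EB": models.fit_eb(tree, scores),
    }
    cfg = shift_results[tag]
    if cfg.n_shifts:
        painting = sh.config_to_painting(tree, cfg)
        fits["shift_model"] = models.fit_oum(tree, scores, painting)
    if states is not None:
        for col in states.columns[1:]:
            tip_states = dict(zip(states.iloc[:, 0].astype(str), states[col].astype(str)))
            maps = models.simmap(tree, tip_states, n_maps=100,
                                 seed=config.seed + 7)
            fits[f"OU-{col.upper()}"] = [models.fit_oum(tree, scores, m)
                                         for m in maps]
    table = models.compare_models(fits)
    table.to_csv(outdir / "model_comparison.csv", index=False)
    results["model_table"] = table

    manifest["stages"]["complete"] = True
    _write_json(outdir / "manifest.json", manifest)
    return results
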