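"""End-to-end pipeline orchestration with a reproducible run manifest.

Stages communicate through files under the run directory (``tables/``,
``figures/``, ``manifest.json``), so any stage can be re-run or inspected
independently.  The manifest records the config snapshot, input checksums,
seeds, per-stage status and every output file with its checksum — and is
written even when a stage fails (downstream stages are skipped).
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cnv import cluster_subclones, cnv_profile
from .graph import build_grid_graph, build_radius_graph, build_delaunay_graph
from .io import (
    read_gene_positions,
    read_gmt,
    read_marker_table,
    read_spot_dataset,
)
from .scoring import cell_type_scores, pathway_scores
from .spatial_models import fit_all_pathways, pvalue_matrix, spca
from .spatial_stats import morans_i_test, semivariogram

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "default_config"]


def default_config() -> dict:
    return {
        "input": {},               # counts, coords, markers, genesets, positions
        "min_counts": 1,
        "seed": 0,
        "graph": {"method": "grid", "adjacency": "queen", "radius": 1.5},
        "scoring": {"top_frac": 0.05},
        "stats": {"n_perm": 999, "d_max": 6, "min_pairs": 30, "weights": "binary"},
        "lag": {"enabled": True},
        "cnv": {
            "enabled": True,
            "window": 101,
            "clip": 1.0,
            "tumor_feature": "tumor",
            "tumor_quantile": 0.5,
            "k_range": [2, 4],
        },
        "figures": True,
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    inputs: dict = field(default_factory=dict)      # path -> checksum
    stages: dict = field(default_factory=dict)      # name -> {status, outputs, error}
    outputs: dict = field(default_factory=dict)     # path -> checksum

    def record(self, stage: str, status: str, outputs=(), error: str | None = None):
        self.stages[stage] = {
            "status": status,
            "outputs": [str(p) for p in outputs],
            **({"error": error} if error else {}),
        }
        for p in outputs:
            if Path(p).exists():
                self.outputs[str(p)] = _sha256(p)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "config": self.config,
                    "inputs": self.inputs,
                    "stages": self.stages,
                    "outputs": self.outputs,
                },
                fh,
                indent=2,
                default=str,
            )


def _build_graph(dataset, gcfg):
    method = gcfg.get("method", "grid")
    if method == "grid":
        return build_grid_graph(dataset, adjacency=gcfg.get("adjacency", "queen"))
    if method == "radius":
        return build_radius_graph(dataset, radius=float(gcfg.get("radius", 1.5)))
    if method == "delaunay":
        return build_delaunay_graph(dataset, max_edge_len=float(gcfg.get("max_edge_len", np.inf)))
    raise ValueError(f"unknown graph method {method!r}")


def _score_map_figure(dataset, values, title, path):
    fig, ax = plt.subplots(figsize=(5, 4.5))
    sc = ax.scatter(dataset.coords[:, 0], dataset.coords[:, 1], c=values, s=36, cmap="viridis")
    ax.set_aspect("equal")
    ax.set_title(title)
    ax.set_xlabel("array x")
    ax.set_ylabel("array y")
    fig.colorbar(sc, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_pipeline(config, out_dir) -> RunManifest:
    """Execute the full analysis described by ``config`` into ``out_dir``.

    ``config`` is a dict or a YAML path; unset keys take defaults from
    :func:`default_config`.  Fatal stage errors are recorded in the manifest
    and downstream stages are skipped, never silently swallowed.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merge(default_config(), config)
    out = Path(out_dir)
    tables = out / "tables"
    figures = out / "figures"
    tables.mkdir(parents=True, exist_ok=True)
    figures.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg)
    manifest_path = out / "manifest.json"

    state: dict = {}
    try:
        _run_stages(cfg, tables, figures, manifest, state)
    finally:
        manifest.write(manifest_path)
    return manifest


def _run_stages(cfg, tables, figures, manifest, state) -> None:
    inp = cfg["input"]
    for key in ("counts", "coords", "markers", "genesets", "positions"):
        p = inp.get(key)
        if p and Path(p).exists():
            manifest.inputs[str(p)] = _sha256(p)

    failed = False

    def stage(name, enabled=True):
        def deco(fn):
            nonlocal failed
            if failed:
                manifest.record(name, "skipped-upstream-failure")
                return
            if not enabled:
                manifest.record(name, "skipped")
                return
            try:
                outputs = fn() or []
                manifest.record(name, "ok", outputs)
            except Exception as exc:  # recorded, not raised: partial runs are valid
                logger.error("stage %s failed: %s", name, exc)
                logger.debug(traceback.format_exc())
                manifest.record(name, "failed", error=str(exc))
                failed = True
        return deco

    @stage("data_io")
    def _load():
        dataset = read_spot_dataset(
            inp["counts"], inp["coords"], min_counts=int(cfg["min_counts"])
        )
        state["dataset"] = dataset
        state["markers"] = read_marker_table(inp["markers"])
        if inp.get("genesets"):
            state["genesets"] = read_gmt(inp["genesets"])
        if inp.get("positions"):
            state["positions"] = read_gene_positions(inp["positions"])
        return []

    @stage("graph")
    def _graph():
        graph = _build_graph(state["dataset"], cfg["graph"])
        state["graph"] = graph
        p = tables / "graph_edges.tsv"
        graph.write_edge_list(p)
        return [p]

    @stage("scoring")
    def _score():
        outs = []
        ct = cell_type_scores(state["dataset"], state["markers"])
        state["celltypes"] = ct
        p = tables / "cell_type_scores.tsv"
        ct.write(p)
        outs += [p, Path(f"{p}.json")]
        if "genesets" in state:
            pw = pathway_scores(
                state["dataset"], state["genesets"],
                top_frac=float(cfg["scoring"]["top_frac"]), seed=int(cfg["seed"]),
            )
            state["pathways"] = pw
            p = tables / "pathway_scores.tsv"
            pw.write(p)
            outs += [p, Path(f"{p}.json")]
        return outs

    @stage("spatial_stats")
    def _stats():
        scfg = cfg["stats"]
        rows, vario_rows = [], []
        for label in ("celltypes", "pathways"):
            if label not in state:
                continue
            table = state[label]
            for feat in table.features:
                x = table.vector(feat)
                res = morans_i_test(
                    x, state["graph"], n_perm=int(scfg["n_perm"]),
                    seed=int(cfg["seed"]), weights=scfg["weights"], feature=feat,
                )
                rows.append({"table": label, **res.to_row()})
                v = semivariogram(
                    x, state["graph"], d_max=int(scfg["d_max"]),
                    min_pairs=int(scfg["min_pairs"]),
                )
                vf = v.to_frame()
                vf.insert(0, "feature", feat)
                vf.insert(0, "table", label)
                vf["gamma_ratio"] = v.ratio_to_first_lag()
                vario_rows.append(vf)
        p1 = tables / "morans_i.tsv"
        pd.DataFrame(rows).to_csv(p1, sep="\t", index=False)
        p2 = tables / "variograms.tsv"
        pd.concat(vario_rows, ignore_index=True).to_csv(p2, sep="\t", index=False)
        state["moran_table"] = pd.DataFrame(rows)
        state["variograms"] = pd.concat(vario_rows, ignore_index=True)
        return [p1, p2]

    @stage("spca")
    def _spca():
        outs = []
        for label in ("celltypes", "pathways"):
            if label not in state:
                continue
            res = spca(state[label], state["graph"])
            state[f"spca_{label}"] = res
            load_p = tables / f"spca_{label}_loadings.tsv"
            res.loadings.to_csv(load_p, sep="\t")
            eig_p = tables / f"spca_{label}_eigenvalues.tsv"
            pd.DataFrame(
                {
                    "eigenvalue": res.eigenvalues,
                    "variance_part": res.variance_part,
                    "moran_part": res.moran_part,
                },
                index=res.loadings.columns,
            ).to_csv(eig_p, sep="\t")
            outs += [load_p, eig_p]
        return outs

    @stage("lag_models", enabled=bool(cfg["lag"]["enabled"]))
    def _lag():
        if "pathways" not in state:
            logger.info("no pathway scores; lag models not fit")
            return []
        fits, long = fit_all_pathways(state["pathways"], state["celltypes"], state["graph"])
        state["lag_fits"] = fits
        p1 = tables / "lag_coefficients.tsv"
        long.to_csv(p1, sep="\t", index=False)
        p2 = tables / "lag_pvalue_matrix.tsv"
        pvalue_matrix(long).to_csv(p2, sep="\t")
        meta = {
            pw: {
                "rho": fit.rho,
                "sigma2": fit.sigma2,
                "loglik": fit.loglik,
                "boundary_warning": fit.boundary_warning,
            }
            for pw, fit in fits.items()
        }
        p3 = tables / "lag_fit_meta.json"
        with open(p3, "w") as fh:
            json.dump(meta, fh, indent=2)
        return [p1, p2, p3]

    @stage("cnv", enabled=bool(cfg["cnv"]["enabled"]))
    def _cnv():
        if "positions" not in state:
            logger.info("no gene positions; CNV stage not run")
            return []
        ccfg = cfg["cnv"]
        ct = state["celltypes"]
        tumor_feature = ccfg["tumor_feature"]
        score = ct.values[tumor_feature]
        thr = score.quantile(float(ccfg["tumor_quantile"]))
        reference = [b for b in ct.barcodes if score.loc[b] <= thr]
        profile = cnv_profile(
            state["dataset"], state["positions"], reference,
            window=int(ccfg["window"]), clip=float(ccfg["clip"]),
        )
        coords = pd.DataFrame(
            state["dataset"].coords, index=state["dataset"].barcodes, columns=["x", "y"]
        )
        sm = cluster_subclones(
            profile, ct, tumor_feature=tumor_feature,
            k_range=tuple(ccfg["k_range"]),
            tumor_quantile=float(ccfg["tumor_quantile"]),
            coords=coords,
        )
        state["subclones"] = sm
        p1 = tables / "cnv_matrix.tsv"
        profile.to_csv(p1, sep="\t")
        p2 = tables / "subclones.tsv"
        sm.to_frame().to_csv(p2, sep="\t")
        return [p1, p2]

    @stage("figures", enabled=bool(cfg["figures"]))
    def _figures():
        outs = []
        dataset = state["dataset"]
        ct = state.get("celltypes")
        if ct is not None:
            for feat in ct.features[:4]:
                p = figures / f"score_map_{feat}.png"
                _score_map_figure(dataset, ct.vector(feat), f"{feat} abundance", p)
                outs.append(p)
        if "variograms" in state:
            fig, ax = plt.subplots(figsize=(5, 4))
            vg = state["variograms"]
            for feat, sub in vg[vg["table"] == "celltypes"].groupby("feature"):
                ax.plot(sub["d"], sub["gamma"], marker="o", label=feat)
            ax.set_xlabel("graph distance (spots)")
            ax.set_ylabel("semivariance")
            ax.legend(fontsize=7)
            fig.tight_layout()
            p = figures / "variograms.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            outs.append(p)
        res = state.get("spca_celltypes")
        if res is not None:
            fig, ax = plt.subplots(figsize=(5, 5))
            L = res.loadings
            for name in L.index:
                ax.annotate(name, (0, 0), (L.loc[name, "sPC1"], L.loc[name, "sPC2"]),
                            arrowprops=dict(arrowstyle="<-", lw=0.8))
            lim = float(np.abs(L[["sPC1", "sPC2"]].to_numpy()).max()) * 1.2
            ax.set_xlim(-lim, lim)
            ax.set_ylim(-lim, lim)
            ax.axhline(0, lw=0.5, color="gray")
            ax.axvline(0, lw=0.5, color="gray")
            ax.set_xlabel("sPC1 loading")
            ax.set_ylabel("sPC2 loading")
            fig.tight_layout()
            p = figures / "spca_celltypes_loadings.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            outs.append(p)
        if "lag_fits" in state:
            long = pd.read_csv(tables / "lag_coefficients.tsv", sep="\t")
            mat = pvalue_matrix(long)
            fig, ax = plt.subplots(figsize=(5, 3.5))
            im = ax.imshow(-np.log10(mat.to_numpy(dtype=float)), cmap="magma", aspect="auto")
            ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right", fontsize=7)
            ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=7)
            fig.colorbar(im, ax=ax, label="-log10 p")
            fig.tight_layout()
            p = figures / "lag_pvalue_heatmap.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            outs.append(p)
        if "subclones" in state:
            sm = state["subclones"]
            frame = sm.to_frame()
            fig, ax = plt.subplots(figsize=(5, 4.5))
            sc = ax.scatter(frame["x"], frame["y"], c=frame["subclone"], s=36, cmap="tab10")
            ax.set_aspect("equal")
            ax.set_title(f"subclones (K={sm.k})")
            fig.colorbar(sc, ax=ax, shrink=0.8)
            fig.tight_layout()
            p = figures / "subclone_map.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            outs.append(p)
        return outs
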