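"""End-to-end orchestration: synthetic data -> preprocessing -> PARAFAC ->
indices -> 2D-COS -> microbiome -> network -> path model.

The pipeline is a pure function of its configuration and seeds: the
report payload is byte-identical across reruns with the same config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import eem as eem_mod
from . import indices as idx_mod
from . import microbiome as micro_mod
from . import network as net_mod
from . import parafac as pf_mod
from . import pathmodel as path_mod
from . import synthetic as syn_mod
from . import twodcos as cos_mod

logger = logging.getLogger("riverdom.pipeline")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Parameters for a full synthetic-data pipeline run."""

    output_dir: str = "riverdom_out"
    seed: int = 0
    season: str = "recovery"          # fluorophore set: dry | wet | recovery
    n_samples: int = 20
    n_taxa: int = 40
    depth: int = 20000
    noise_sd: float | None = None     # default: 1% of peak signal
    scatter: bool = True
    n_components: int | None = None   # default: number of fluorophores
    n_starts: int = 4
    tol: float = 1e-8
    max_iter: int = 800
    r_min: float = 0.5
    p_max: float = 0.05
    ex_hix: float = 254.0
    zero_tol: float = 0.05
    order_variable: str = "sample_id"  # 2D-COS perturbation ordering

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def fluorophores_for(season: str) -> list[syn_mod.FluorophoreSpec]:
    sets = {"dry": syn_mod.dry_season_fluorophores,
            "wet": syn_mod.wet_season_fluorophores,
            "recovery": syn_mod.recovery_fluorophores}
    if season not in sets:
        raise ConfigError(f"unknown season {season!r}; choose from "
                          f"{sorted(sets)}")
    return sets[season]()


def synthetic_blank(ex: np.ndarray, em: np.ndarray,
                    amplitude: float) -> eem_mod.EEMSpectrum:
    """Pure-water blank: scatter ridges only (Rayleigh + Raman), no DOM."""
    grid = syn_mod._scatter_ridges(np.asarray(ex, float),
                                   np.asarray(em, float), amplitude)
    return eem_mod.EEMSpectrum(ex=ex, em=em, intensity=grid,
                               sample_id="blank")


def _protein_humic_split(peak_table: pd.DataFrame) -> tuple[list[str], list[str]]:
    protein = list(peak_table.index[peak_table["class"] == "protein-like"])
    humic = list(peak_table.index[peak_table["class"] == "humic-like"])
    return protein, humic


def generic_path_spec(peak_table: pd.DataFrame,
                      phyla: list[str]) -> path_mod.PathSpec:
    """Path structure from fitted components: microbes act on the protein
    and humic blocks, which drive the humification ratio."""
    protein, humic = _protein_humic_split(peak_table)
    if not protein or not humic:
        raise ConfigError("path model needs both protein-like and "
                          "humic-like components")
    return path_mod.PathSpec(
        composites={"Microbes": phyla, "Protein": protein, "Humic": humic},
        paths=[("Microbes", "Protein"), ("Microbes", "Humic"),
               ("Protein", "Humification"), ("Humic", "Humification")],
        ratio_composite={"name": "Humification", "numerator": protein,
                         "denominator": humic},
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle.

    Returns the report dict; artifacts (CSV tables, GraphML, DOT, JSON
    report) are written under ``config.output_dir``.
    """
    t0 = time.monotonic()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}

    def stage_done(name: str, started: float) -> None:
        logger.info("stage %-12s finished in %.2f s", name,
                    time.monotonic() - started)

    # -- simulate ----------------------------------------------------
    t = time.monotonic()
    fluors = fluorophores_for(config.season)
    eems, truth = syn_mod.generate_eem_dataset(
        n_samples=config.n_samples, fluorophores=fluors,
        noise_sd=config.noise_sd, scatter=config.scatter, seed=config.seed)
    truth.taxon_links = syn_mod.default_taxon_links(truth)
    truth.chemistry_links = syn_mod.default_chemistry_links(truth)
    otu = syn_mod.generate_otu_table(truth, n_taxa=config.n_taxa,
                                     depth=config.depth, seed=config.seed + 1)
    chem = syn_mod.generate_chemistry(truth, seed=config.seed + 2)
    syn_mod.write_dataset(out / "data", eems, truth, otu, chem)
    report["stages"]["simulate"] = {
        "n_samples": config.n_samples, "n_components_true": len(fluors),
        "seed": config.seed}
    stage_done("simulate", t)

    # -- preprocess --------------------------------------------------
    t = time.monotonic()
    peak = max(float(e.intensity.max()) for e in eems)
    blank = synthetic_blank(eems[0].ex, eems[0].em,
                            amplitude=peak if config.scatter else 0.0)
    processed = []
    raman_areas = []
    for e in eems:
        pe, area = eem_mod.preprocess(e, blank)
        processed.append(pe)
        raman_areas.append(area)
    report["stages"]["preprocess"] = {
        "raman_area": raman_areas[0], "units": "raman_unit",
        "masked_fraction": float(np.mean([p.mask.mean() for p in processed]))}
    stage_done("preprocess", t)

    # -- parafac -----------------------------------------------------
    t = time.monotonic()
    stack = pf_mod.EEMStack(processed)
    rank = config.n_components or len(fluors)
    model = pf_mod.fit_parafac(stack, rank, n_starts=config.n_starts,
                               tol=config.tol, max_iter=config.max_iter,
                               seed=config.seed + 3)
    model.corcondia = pf_mod.corcondia(model, stack)
    model.split_half = pf_mod.split_half_validate(
        stack, rank, seed=config.seed + 4, n_starts=max(2, config.n_starts // 2))
    fmax, percent = pf_mod.compute_fmax(model)
    peak_table = pf_mod.classify_components(model)
    fmax.to_csv(out / "fmax.csv", index_label="sample_id")
    percent.to_csv(out / "percent_abundance.csv", index_label="sample_id")
    report["stages"]["parafac"] = {
        "n_components": rank,
        "explained_variance": model.explained_variance,
        "corcondia": model.corcondia,
        "split_half": model.split_half,
        "mean_percent_abundance": percent.mean(axis=0).round(2).to_dict(),
        "peak_table": {
            c: {"em_peak": row["em_peak"], "ex_peaks": row["ex_peaks"],
                "class": row["class"]}
            for c, row in peak_table.iterrows()},
    }
    stage_done("parafac", t)

    # -- indices -----------------------------------------------------
    t = time.monotonic()
    # indices need the full (unmasked) spectrum: use interpolated scatter fill
    filled = [eem_mod.preprocess(e, blank, fill="interpolate")[0]
              for e in eems]
    idx_table = idx_mod.indices_table(filled, ex_hix=config.ex_hix)
    idx_table.to_csv(out / "indices.csv")
    report["stages"]["indices"] = {
        "mean_fi": float(idx_table["fi"].mean()),
        "mean_bix": float(idx_table["bix"].mean()),
        "mean_hix": float(idx_table["hix"].mean()),
    }
    stage_done("indices", t)

    # -- 2D-COS ------------------------------------------------------
    t = time.monotonic()
    if config.order_variable == "sample_id":
        order = None
    elif config.order_variable in chem.columns:
        order = chem[config.order_variable]
    else:
        raise ConfigError(f"order variable {config.order_variable!r} not "
                          "found in chemistry table")
    series = cos_mod.PerturbationSeries(bands=fmax, order_values=order,
                                        order_name=config.order_variable)
    maps = cos_mod.compute_2dcos(series)
    seq = cos_mod.sequential_order(maps, zero_tol=config.zero_tol)
    maps.phi.to_csv(out / "phi.csv")
    maps.psi.to_csv(out / "psi.csv")
    (out / "sequence.json").write_text(
        json.dumps(seq, indent=1, sort_keys=True), encoding="utf-8")
    report["stages"]["twodcos"] = {
        "order_variable": config.order_variable,
        "sequence": seq["sequence"], "groups": seq["groups"],
        "has_cycle": seq["has_cycle"]}
    stage_done("twodcos", t)

    # -- microbiome --------------------------------------------------
    t = time.monotonic()
    phyla_tab = micro_mod.aggregate_taxonomy(otu, "phylum", top_n=10)
    div = micro_mod.alpha_diversity(otu)
    phyla_tab.to_csv(out / "phylum_abundance.csv")
    pd.DataFrame({"shannon": div.shannon, "chao1": div.chao1,
                  "observed": div.observed}).to_csv(out / "diversity.csv")
    heat = micro_mod.correlate_taxa_components(phyla_tab, fmax)
    heat.to_csv(out / "taxa_component_correlations.csv", index=False)
    report["stages"]["microbiome"] = {
        "mean_shannon": float(div.shannon.mean()),
        "mean_chao1": float(div.chao1.mean()),
        "n_significant_pairs": int((heat["p"] < 0.05).sum()),
    }
    stage_done("microbiome", t)

    # -- network -----------------------------------------------------
    t = time.monotonic()
    rel = otu.counts / otu.counts.sum(axis=0)
    features = pd.concat([rel.T, fmax], axis=1)
    meta = {o: {"phylum": otu.rank_of(o, "phylum")} for o in otu.counts.index}
    net = net_mod.build_network(features, r_min=config.r_min,
                                p_max=config.p_max,
                                component_labels=set(fmax.columns),
                                node_meta=meta)
    summary = net_mod.network_summary(net)
    keystones = net_mod.keystone_taxa(net) if net.n_nodes >= 3 else None
    net_mod.export_graphml(net, out / "network.graphml")
    net_mod.export_edge_list(net, out / "edges.csv")
    report["stages"]["network"] = {
        **summary,
        "keystones": (sorted(keystones.index[keystones["keystone"]])
                      if keystones is not None else []),
    }
    stage_done("network", t)

    # -- path model --------------------------------------------------
    t = time.monotonic()
    phyla_cols = [p for p in syn_mod.PHYLA if p in phyla_tab.index]
    table = pd.concat([phyla_tab.loc[phyla_cols].T, fmax], axis=1)
    spec = generic_path_spec(peak_table, phyla_cols)
    composites = path_mod.build_composites(table, spec)
    pmodel = path_mod.fit_path_model(composites, spec)
    (out / "path_model.dot").write_text(
        path_mod.export_path_diagram(pmodel), encoding="utf-8")
    report["stages"]["pathmodel"] = {
        "n": pmodel.n,
        "coefficients": [
            {k: (round(v, 6) if isinstance(v, float) else v)
             for k, v in row.items()}
            for row in pmodel.coefficients.to_dict("records")],
        "r_squared": {k: round(v, 6) for k, v in pmodel.r_squared.items()},
    }
    stage_done("pathmodel", t)

    payload = json.dumps(report, indent=1, sort_keys=True, default=float)
    (out / "report.json").write_text(payload, encoding="utf-8")
    logger.info("pipeline finished in %.2f s", time.monotonic() - t0)
    return report
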