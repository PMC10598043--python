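"""End-to-end orchestration: simulate/ingest -> classify -> compare.

Every randomized stage draws its seed deterministically from the master
seed and the stage name, so stages produce identical output whether run
standalone or inside :func:`run_all`, and adding a stage never perturbs
another stage's random stream.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import classify_abundance, subgroup_summary
from .compare import anosim, bray_curtis, environment_distance, mantel, nmds, spatial_distance
from .diversity import one_way_anova_letters, subgroup_alpha_table
from .io import read_otu_table, read_sample_metadata, write_otu_table, write_sample_metadata, write_tsv
from .model import SOIL_LAYERS, OtuTable, SampleMetadata, to_relative_abundance
from .niche import classify_niche_table
from .ordination import rda_with_tests
from .simulate import SimulationParams, simulate_community

__all__ = ["RunConfig", "PipelineError", "stage_seed", "run_all"]

logger = logging.getLogger(__name__)

ENV_SETS = ("soil_vars", "plant_diversity", "tree_importance",
            "shrub_importance", "spatial")


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2^31)."""
    return int(
        np.random.SeedSequence(
            [int(master_seed), zlib.crc32(stage.encode())]
        ).generate_state(1)[0] % (2**31)
    )


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    otu_table: str | None = None
    metadata: str | None = None
    orientation: str = "otus_as_rows"
    simulate: dict | None = None  # SimulationParams overrides
    layers: tuple[str, ...] = SOIL_LAYERS
    hi: float = 0.01
    lo: float = 0.0001
    niche_method: str = "replacement_multinomial"
    niche_n_perm: int = 1000
    tests: tuple[str, ...] = ("anosim", "mantel", "nmds")
    n_perm: int = 999
    rda_sets: tuple[str, ...] = ("soil_vars", "plant_diversity")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("layers", "tests", "rda_sets"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.seed is None:
            raise PipelineError("config", "missing_seed", "seed is mandatory")
        if (self.otu_table is None) != (self.metadata is None):
            raise PipelineError(
                "config", "partial_input",
                "otu_table and metadata must be given together",
            )
        for path in (self.otu_table, self.metadata):
            if path is not None and not os.path.exists(path):
                raise PipelineError(
                    "config", "missing_path", f"input path {path!r} does not exist"
                )
        if "mantel" in self.tests and self.otu_table is not None and self.metadata is None:
            raise PipelineError(
                "config", "missing_metadata",
                "mantel requires a metadata table",
            )
        unknown = set(self.layers) - set(SOIL_LAYERS)
        if unknown:
            raise PipelineError(
                "config", "bad_layer", f"unknown layer(s) {sorted(unknown)}"
            )


def _load_inputs(config: RunConfig):
    if config.otu_table is not None:
        table = read_otu_table(config.otu_table, orientation=config.orientation)
        meta = read_sample_metadata(config.metadata)
        return table, meta, None
    overrides = dict(config.simulate or {})
    overrides.setdefault("seed", stage_seed(config.seed, "simulate"))
    params = SimulationParams(**overrides)
    sim = simulate_community(params)
    return sim.table, sim.metadata, sim.truth


def _stand_anova(alpha: pd.DataFrame, meta: SampleMetadata,
                 metric: str = "shannon") -> pd.DataFrame:
    """Per-subgroup one-way ANOVA of a diversity metric across stand types."""
    rows = []
    stands = meta.stand_type
    for subgroup, sub in alpha.groupby(level="subgroup"):
        values = sub.droplevel("subgroup")[metric]
        by_group = {
            s: values.reindex(stands.index[stands == s]).to_numpy()
            for s in stands.unique()
        }
        try:
            res = one_way_anova_letters(by_group)
        except ValueError:
            continue
        for stand, rec in res["summary"].iterrows():
            rows.append({
                "subgroup": subgroup, "stand_type": stand, "metric": metric,
                "n": rec["n"], "mean": rec["mean"], "sd": rec["sd"],
                "letters": rec["letters"], "F": res["F"], "p": res["p"],
            })
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Execute the full dual-gradient analysis; returns the report bundle.

    Writes per-stage TSVs under ``config.out_dir`` and a manifest recording
    versions, seeds and parameters.  Stage failures raise
    :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    provenance = {"seed": config.seed, "version": __version__}

    table, meta, truth = _load_inputs(config)
    write_otu_table(table, out / "otu_table.tsv", params=provenance)
    write_sample_metadata(meta, out / "metadata.tsv", params=provenance)
    if truth is not None:
        write_tsv(truth, out / "truth.tsv", params=provenance,
                  index_label="otu_id")
    report["table"], report["metadata"], report["truth"] = table, meta, truth

    for layer in config.layers:
        tag = layer
        samples = meta.samples_in_layer(layer)
        if not samples:
            logger.warning("no samples in layer %r; skipped", layer)
            continue
        sub_table, n_dropped = table.subset_samples(samples).drop_empty_otus()
        rel = to_relative_abundance(sub_table)
        layer_report: dict = {"n_empty_otus": n_dropped}
        report[layer] = layer_report

        try:
            abund = classify_abundance(rel, hi=config.hi, lo=config.lo)
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError("classify-abundance", "failed", str(exc))
        write_tsv(abund.assignments, out / f"abundance_{tag}.tsv",
                  params={**provenance, "hi": config.hi, "lo": config.lo},
                  index_label="otu_id")
        summary = subgroup_summary(sub_table, abund)
        write_tsv(summary, out / f"abundance_summary_{tag}.tsv",
                  params=provenance)
        layer_report["abundance"] = abund
        layer_report["abundance_summary"] = summary

        niche_seed = stage_seed(config.seed, f"niche:{layer}")
        try:
            niche = classify_niche_table(
                sub_table, n_perm=config.niche_n_perm,
                method=config.niche_method, seed=niche_seed,
            )
        except Exception as exc:
            raise PipelineError("classify-niche", "failed", str(exc))
        write_tsv(niche.assignments, out / f"niche_{tag}.tsv",
                  params={**provenance, "n_perm": config.niche_n_perm,
                          "method": config.niche_method,
                          "stage_seed": niche_seed},
                  index_label="otu_id")
        layer_report["niche"] = niche

        niche_counts = table.subset_samples(samples).counts[niche.otu_ids]
        niche_share = pd.DataFrame({
            "otu_fraction": niche.niche_class.value_counts(normalize=True),
            "read_fraction": niche_counts.T.groupby(niche.niche_class).sum()
            .sum(axis=1) / niche_counts.to_numpy().sum(),
        })
        write_tsv(niche_share, out / f"niche_summary_{tag}.tsv",
                  params=provenance, index_label="niche_class")
        layer_report["niche_summary"] = niche_share

        sub_meta = meta.subset(samples)
        for gradient, groups in (("abundance", abund.groups()),
                                 ("niche", niche.groups())):
            alpha = subgroup_alpha_table(sub_table, groups)
            write_tsv(alpha.reset_index().set_index("sample_id"),
                      out / f"alpha_{gradient}_{tag}.tsv", params=provenance)
            anova = _stand_anova(alpha, sub_meta)
            if len(anova):
                write_tsv(anova.set_index("subgroup"),
                          out / f"alpha_anova_{gradient}_{tag}.tsv",
                          params=provenance)
            layer_report[f"alpha_{gradient}"] = alpha
            layer_report[f"alpha_anova_{gradient}"] = anova

        comparison_rows = []
        for gradient, groups in (("abundance", abund.groups()),
                                 ("niche", niche.groups())):
            for subgroup, otus in groups.items():
                if len(otus) < 2:
                    continue
                counts = sub_table.counts[otus]
                keep = counts.sum(axis=1) > 0
                if keep.sum() < 4 or sub_meta.stand_type[keep].nunique() < 2:
                    continue
                dist = bray_curtis(
                    OtuTable(counts.loc[keep]), on_counts=False
                )
                seed_tag = f"{gradient}:{subgroup}:{layer}"
                if "nmds" in config.tests:
                    ord_res = nmds(dist, seed=stage_seed(config.seed,
                                                         "nmds:" + seed_tag))
                    write_tsv(ord_res.coordinates,
                              out / f"nmds_{gradient}_{subgroup}_{tag}.tsv",
                              params={**provenance, "stress": ord_res.stress},
                              index_label="sample_id")
                if "anosim" in config.tests:
                    stands = sub_meta.stand_type[keep]
                    ok = stands.map(stands.value_counts()) >= 2
                    if stands[ok].nunique() >= 2:
                        res = anosim(
                            _filter_distance(dist, list(stands.index[ok])),
                            stands[ok], n_perm=config.n_perm,
                            seed=stage_seed(config.seed, "anosim:" + seed_tag),
                        )
                        comparison_rows.append({
                            "gradient": gradient, "subgroup": subgroup,
                            "test": "anosim", "factor": "stand_type",
                            "statistic": res.statistic, "p": res.p_value,
                        })
                if "mantel" in config.tests:
                    for env in ENV_SETS:
                        env_d = (spatial_distance(sub_meta) if env == "spatial"
                                 else environment_distance(sub_meta, env))
                        if env_d is None:
                            continue
                        env_d = _filter_distance(env_d, list(dist.ids))
                        res = mantel(
                            dist, env_d, n_perm=config.n_perm,
                            seed=stage_seed(config.seed,
                                            f"mantel:{env}:" + seed_tag),
                        )
                        comparison_rows.append({
                            "gradient": gradient, "subgroup": subgroup,
                            "test": "mantel", "factor": env,
                            "statistic": res.statistic, "p": res.p_value,
                        })
        if comparison_rows:
            comp = pd.DataFrame(comparison_rows)
            write_tsv(comp.set_index("subgroup"),
                      out / f"comparisons_{tag}.tsv", params=provenance)
            layer_report["comparisons"] = comp

        rda_rows = []
        for gradient, groups in (("abundance", abund.groups()),
                                 ("niche", niche.groups())):
            for subgroup, otus in groups.items():
                if len(otus) < 2:
                    continue
                counts = sub_table.counts[otus]
                keep = counts.sum(axis=1) > 0
                for env in config.rda_sets:
                    x = sub_meta.variable_group(env)
                    if x is None:
                        continue
                    x = x.loc[keep[keep].index]
                    y = counts.loc[keep]
                    if y.shape[0] <= x.shape[1] + 1:
                        logger.warning(
                            "rda %s/%s/%s skipped: too few samples",
                            gradient, subgroup, env,
                        )
                        continue
                    res = rda_with_tests(
                        y, x, n_perm=config.n_perm,
                        seed=stage_seed(config.seed,
                                        f"rda:{env}:{gradient}:{subgroup}:{layer}"),
                    )
                    rda_rows.append({
                        "gradient": gradient, "subgroup": subgroup,
                        "explanatory": env,
                        "constrained_fraction": res.constrained_fraction,
                        "model_p": res.model_p,
                    })
        if rda_rows:
            rda_df = pd.DataFrame(rda_rows)
            write_tsv(rda_df.set_index("subgroup"),
                      out / f"rda_{tag}.tsv", params=provenance)
            layer_report["rda"] = rda_df

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    report["manifest"] = manifest
    return report


def _filter_distance(d, ids):
    """Restrict a distance matrix to a subset of ids (order preserved)."""
    return d.filter(ids)
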