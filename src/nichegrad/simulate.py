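"""Synthetic soil bacterial communities with planted ground truth.

The generator emulates the sampling design the analysis modules expect:
20 quadrats spread over four stand types (shrub S, coniferous CF, mixed MF
and broad-leaved BF forest, 3/3/3/11 quadrats), two soil layers per
quadrat, per-sample sequencing depths drawn uniformly from a realistic
range, and a lognormal community abundance spectrum.  Every OTU carries a
planted niche archetype (generalist / neutral / specialist) and a planted
abundance class (abundant / medium / rare), recorded in a truth table so
downstream classifiers can be scored against known labels.

Planted structure
-----------------
* **Abundance classes** are expected relative-abundance (RA) bands chosen
  so the 1% / 0.01% threshold classifier can recover them: abundant OTUs
  sit above 1% RA in expectation, rare OTUs below 0.01%, medium in between.
* **Specialists** concentrate their reads in a randomly chosen home set of
  stand types: the expected abundance is ``habitat_effect``-fold higher in
  home stands than elsewhere, with the OTU's total expected mass preserved.
* **Generalists** have equal expected *reads* in every sample, which makes
  their occupancy profile strictly more even than the depth-proportional
  multinomial null used by the niche classifier.
* **Neutrals** have equal expected *relative abundance* in every sample,
  i.e. reads proportional to sample depth - exactly the null's expectation.

Counts are drawn multinomially per sample at the sample's depth, which
preserves the compositional coupling between OTUs that the relative
abundance thresholds act on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import OtuTable, SampleMetadata, STAND_TYPES

__all__ = [
    "SimulationParams",
    "SimulatedCommunity",
    "simulate_community",
    "simulate_covariates",
]

ARCHETYPES = ("generalist", "neutral", "specialist")
ABUNDANCE_CLASSES = ("abundant", "medium", "rare")

# Expected-RA bands (fractions, pre-normalization) per planted block.
# Chosen once from an identifiability analysis of the niche null model:
# generalists must carry >~3000 reads per layer to be separable from the
# null, specialists stay separable down to ~50 reads (see docs/methods.md).
_BANDS = {
    ("abundant", "any"): (0.012, 0.022),
    ("medium", "generalist"): (0.003, 0.007),
    ("medium", "other"): (0.0005, 0.009),
    ("rare", "any"): (0.00005, 0.000099),
}

_TREE_SPECIES = (
    "Pinus_densiflora", "Pinus_tabuliformis", "Platycladus_orientalis",
    "Populus_davidiana", "Robinia_pseudoacacia", "Quercus_acutissima",
    "Diospyros_lotus", "Koelreuteria_paniculata",
)
_SHRUB_SPECIES = (
    "Vitex_negundo", "Ziziphus_jujuba", "Grewia_biloba", "Morus_mongolica",
)

# Dirichlet preference weights per stand type over the species pools.
_TREE_PREFS = {
    "S": (0.2, 0.2, 0.2, 0.5, 0.5, 0.3, 0.2, 0.2),
    "CF": (8, 8, 2, 0.3, 0.3, 0.3, 0.2, 0.2),
    "MF": (5, 3, 1, 3, 2, 3, 1, 0.5),
    "BF": (0.3, 0.3, 0.5, 4, 6, 4, 2, 1),
}
_SHRUB_PREFS = {
    "S": (8, 3, 2, 1),
    "CF": (3, 2, 1, 0.5),
    "MF": (2, 2, 1.5, 1),
    "BF": (2, 1, 1.5, 2),
}

# Stand-level soil offsets (in units of the variable's within-stand sd),
# loosely echoing the direction of the field contrasts: broad-leaved
# forests higher in pH and NH4-N, conifers higher in organic C and NO3-N.
_SOIL_VARS = ("dry_matter", "available_P", "organic_C",
              "NH4_N", "NO3_N", "NO2_N", "pH")
_SOIL_BASELINE = {
    "dry_matter": (0.984, 0.004),
    "available_P": (4.3, 1.6),
    "organic_C": (3.5, 0.8),
    "NH4_N": (12.5, 2.0),
    "NO3_N": (7.6, 1.7),
    "NO2_N": (4.3, 1.2),
    "pH": (4.92, 0.30),
}
_SOIL_OFFSETS = {
    "S": {"available_P": 2.0, "organic_C": -1.0, "pH": 0.3},
    "CF": {"organic_C": 0.7, "NO3_N": 0.5, "pH": -0.7},
    "MF": {"organic_C": 0.5, "pH": -0.6},
    "BF": {"available_P": -0.8, "NH4_N": 0.8, "NO2_N": -0.4, "pH": 1.0},
}
_SUBSOIL_SHIFT = {"organic_C": -1.8, "NH4_N": -0.8, "NO3_N": -0.6,
                  "NO2_N": -0.8}


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic community design (defaults = study design)."""

    n_stand_types: int = 4
    quadrats_per_stand: tuple[int, ...] = (3, 3, 3, 11)
    n_layers: int = 2
    n_otus: int = 1200
    archetype_fractions: tuple[float, float, float] = (0.05, 0.30, 0.65)
    abundance_class_fractions: tuple[float, float, float] = (0.03, 0.07, 0.90)
    lognormal_sigma: float = 1.0
    depth_range: tuple[int, int] = (46595, 73284)
    specialist_occupancy: int = 1
    habitat_effect: float = 100.0
    layer_sigma: float = 0.15
    coordinate_box: tuple[tuple[float, float], ...] = (
        (117.41, 117.57), (36.40, 36.49), (300.0, 760.0))
    covariate_effect: float = 1.0
    soil_offsets: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.quadrats_per_stand) != self.n_stand_types:
            raise ValueError("quadrats_per_stand length must equal n_stand_types")
        if self.n_stand_types > len(STAND_TYPES):
            raise ValueError(f"at most {len(STAND_TYPES)} stand types supported")
        for name in ("archetype_fractions", "abundance_class_fractions"):
            fr = getattr(self, name)
            if len(fr) != 3 or any(f < 0 for f in fr) or abs(sum(fr) - 1) > 1e-9:
                raise ValueError(f"{name} must be three non-negative values summing to 1")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError("depth_range must be positive and ordered")
        if not (1 <= self.specialist_occupancy <= self.n_stand_types):
            raise ValueError("specialist_occupancy must be in [1, n_stand_types]")
        if self.habitat_effect < 0:
            raise ValueError("habitat_effect must be >= 0")

    @property
    def stand_types(self) -> tuple[str, ...]:
        return STAND_TYPES[: self.n_stand_types]


@dataclass
class SimulatedCommunity:
    """Bundle returned by :func:`simulate_community`."""

    table: OtuTable
    metadata: SampleMetadata
    truth: pd.DataFrame
    #: expected per-sample relative abundances (samples x OTUs), the
    #: closed-form plan the multinomial draws are taken from
    expected: pd.DataFrame = field(repr=False, default=None)

    def __iter__(self):
        return iter((self.table, self.metadata, self.truth))


def _largest_remainder(total: int, fractions) -> np.ndarray:
    raw = np.asarray(fractions, dtype=float) * total
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    for k in order[: total - counts.sum()]:
        counts[k] += 1
    return counts


def _allocate_labels(p: SimulationParams, rng) -> tuple[np.ndarray, np.ndarray]:
    """Joint archetype x abundance-class assignment.

    Generalists occupy the upper-medium band (they must be well sampled to
    be identifiable against the null); specialists split between the rare
    and abundant classes in proportion to available slots; neutrals fill
    the remainder.  Raises on infeasible fraction combinations.
    """
    n = p.n_otus
    n_class = _largest_remainder(n, p.abundance_class_fractions)
    n_arch = _largest_remainder(n, p.archetype_fractions)
    n_ab, n_med, n_rare = n_class
    n_gen, n_neu, n_spec = n_arch

    if n_gen > n_med:
        raise ValueError(
            f"infeasible class targets: {n_gen} generalists need medium-band "
            f"slots but only {n_med} medium OTUs are planned"
        )
    n_spec_ab = min(n_ab, int(round(n_spec * n_ab / max(n_ab + n_rare, 1))))
    n_spec_rare = min(n_rare, n_spec - n_spec_ab)
    # specialists overflow into medium slots not taken by generalists
    n_spec_med = n_spec - n_spec_ab - n_spec_rare
    if n_spec_med > n_med - n_gen:
        extra = n_spec_med - (n_med - n_gen)
        n_spec_ab = min(n_ab, n_spec_ab + extra)
        n_spec_med = n_spec - n_spec_ab - n_spec_rare
        if n_spec_med > n_med - n_gen:
            raise ValueError("infeasible class targets: archetypes exceed slots")

    classes = np.array(
        ["abundant"] * n_ab + ["medium"] * n_med + ["rare"] * n_rare,
        dtype=object,
    )
    archetypes = np.empty(n, dtype=object)
    archetypes[:n_ab] = "neutral"
    spec_ab_idx = rng.choice(n_ab, size=n_spec_ab, replace=False) if n_spec_ab else []
    archetypes[spec_ab_idx] = "specialist"
    med_idx = np.arange(n_ab, n_ab + n_med)
    archetypes[med_idx] = "neutral"
    picked = rng.choice(med_idx, size=n_gen + n_spec_med, replace=False) \
        if n_gen + n_spec_med else np.array([], dtype=int)
    archetypes[picked[:n_gen]] = "generalist"
    archetypes[picked[n_gen:]] = "specialist"
    rare_idx = np.arange(n_ab + n_med, n)
    archetypes[rare_idx] = "neutral"
    spec_rare_idx = (
        rng.choice(rare_idx, size=n_spec_rare, replace=False) if n_spec_rare else []
    )
    archetypes[spec_rare_idx] = "specialist"
    return classes, archetypes


def _band_for(klass: str, archetype: str) -> tuple[float, float]:
    if klass == "medium":
        key = "generalist" if archetype == "generalist" else "other"
        return _BANDS[("medium", key)]
    return _BANDS[(klass, "any")]


def _baseline_abundances(classes, archetypes, sigma, rng) -> np.ndarray:
    """Lognormal baseline RA per OTU, rank-mapped into its planted band."""
    n = len(classes)
    b = np.empty(n)
    raw = rng.lognormal(0.0, sigma, size=n)
    for klass in ABUNDANCE_CLASSES:
        for arch in ARCHETYPES:
            idx = np.where((classes == klass) & (archetypes == arch))[0]
            if not len(idx):
                continue
            lo, hi = _band_for(klass, arch)
            x = np.log(raw[idx])
            span = x.max() - x.min()
            if span == 0:
                b[idx] = math.sqrt(lo * hi)
            else:
                u = (x - x.min()) / span
                b[idx] = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    total = b.sum()
    if not (0.4 < total < 2.5):
        raise ValueError(
            f"infeasible class targets: planned expected abundances sum to "
            f"{total:.3f}; adjust n_otus or class fractions"
        )
    return b


def _expected_columns(b, archetypes, f_spec, depths) -> np.ndarray:
    """Per-sample expected RA matrix (otus x samples), columns summing to 1.

    Neutrals get depth-independent RA, generalists get depth-compensated RA
    (equal expected reads), and specialists absorb the per-sample slack so
    both guarantees hold exactly after normalization.  Specialist recovery
    is insensitive to the residual per-sample rescaling because their
    home/away contrast dwarfs it.
    """
    n_samples = len(depths)
    is_gen = archetypes == "generalist"
    is_neu = archetypes == "neutral"
    is_spec = archetypes == "specialist"

    dbar_over_d = depths.mean() / depths
    B = b[is_neu].sum()
    G = b[is_gen].sum()
    A_s = f_spec[is_spec].T @ b[is_spec] if is_spec.any() else np.zeros(n_samples)
    lam = 1.0 / (B + G + (A_s.mean() if is_spec.any() else 0.0))

    E = np.empty((len(b), n_samples))
    E[is_neu] = np.outer(b[is_neu], np.full(n_samples, lam))
    E[is_gen] = np.outer(b[is_gen], lam * dbar_over_d)
    if is_spec.any():
        rho = (1.0 - lam * (B + G * dbar_over_d)) / A_s
        if (rho <= 0).any():
            raise ValueError(
                "infeasible class targets: generalist+neutral expected mass "
                "exceeds 1 in some sample"
            )
        E[is_spec] = b[is_spec, None] * f_spec[is_spec] * rho[None, :]
    else:
        E /= E.sum(axis=0, keepdims=True)
    return E


def simulate_community(p: SimulationParams) -> SimulatedCommunity:
    """Generate an OTU table, metadata and truth table for one design.

    Deterministic given ``p.seed``.  Layers share the OTU plan (baseline
    abundances, archetypes, specialist home stands) and differ by
    independent lognormal jitter and independent multinomial noise, so
    topsoil/subsoil contrasts exist without being confounded with stand
    type.
    """
    rng = np.random.default_rng(p.seed)
    stands = p.stand_types

    quadrat_stand = np.repeat(stands, p.quadrats_per_stand)
    n_quadrats = len(quadrat_stand)
    quadrat_ids = [f"Q{i + 1:02d}" for i in range(n_quadrats)]
    layers = ("topsoil", "subsoil")[: p.n_layers]

    classes, archetypes = _allocate_labels(p, rng)
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(p.n_otus)]
    b = _baseline_abundances(classes, archetypes, p.lognormal_sigma, rng)

    # Home stand set per specialist, drawn with probability proportional
    # to the stand's quadrat count so no stand's samples are systematically
    # over- or under-filled by specialist mass.
    is_spec = archetypes == "specialist"
    home_sets = np.zeros((p.n_otus, len(stands)), dtype=bool)
    stand_w = np.asarray(p.quadrats_per_stand, dtype=float)
    stand_w /= stand_w.sum()
    for i in np.where(is_spec)[0]:
        chosen = rng.choice(len(stands), size=p.specialist_occupancy,
                            replace=False, p=stand_w)
        home_sets[i, chosen] = True

    sample_ids, sample_layer, sample_stand = [], [], []
    for layer in layers:
        for q, stand in zip(quadrat_ids, quadrat_stand):
            sample_ids.append(f"{q}_{layer}")
            sample_layer.append(layer)
            sample_stand.append(stand)

    counts = np.zeros((len(sample_ids), p.n_otus), dtype=np.int64)
    expected = np.zeros((len(sample_ids), p.n_otus))
    stand_index = {s: k for k, s in enumerate(stands)}

    for li, layer in enumerate(layers):
        rows = [k for k, l in enumerate(sample_layer) if l == layer]
        n_s = len(rows)
        depths = rng.integers(p.depth_range[0], p.depth_range[1] + 1, n_s)
        b_layer = b * np.exp(rng.normal(0.0, p.layer_sigma, p.n_otus))

        # Specialist modulation: habitat_effect-fold home enrichment with
        # per-OTU mass preserved over the layer's samples.
        home_by_sample = np.array(
            [[home_sets[i, stand_index[sample_stand[k]]] for k in rows]
             for i in range(p.n_otus)]
        )
        f = np.where(home_by_sample, p.habitat_effect, 1.0)
        f /= f.mean(axis=1, keepdims=True)

        E = _expected_columns(b_layer, archetypes, f, depths.astype(float))
        for j, k in enumerate(rows):
            counts[k] = rng.multinomial(depths[j], E[:, j])
            expected[k] = E[:, j]

    table = OtuTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids))
    meta_frame = pd.DataFrame(
        {
            "quadrat": [s.split("_")[0] for s in sample_ids],
            "stand_type": sample_stand,
            "soil_layer": sample_layer,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    metadata = SampleMetadata(meta_frame)
    metadata = simulate_covariates(p, metadata, rng=rng)

    truth = pd.DataFrame(
        {
            "archetype": archetypes,
            "abundance_class": classes,
            "home_stands": [
                ",".join(s for k, s in enumerate(stands) if home_sets[i, k])
                for i in range(p.n_otus)
            ],
        },
        index=pd.Index(otu_ids, name="otu_id"),
    )
    expected_df = pd.DataFrame(expected, index=sample_ids, columns=otu_ids)
    return SimulatedCommunity(table, metadata, truth, expected_df)


def _plant_diversity_indices(importance: np.ndarray) -> dict[str, float]:
    """Vegetation alpha-diversity from an importance-value vector.

    Uses the plug-in (proportion-based) Simpson form since importance
    values are not integer counts.
    """
    p_pos = importance[importance > 0]
    p_pos = p_pos / p_pos.sum()
    m = len(p_pos)
    shannon = float(-(p_pos * np.log(p_pos)).sum())
    simpson = float(1.0 - (p_pos**2).sum())
    logm = math.log(m) if m >= 2 else np.nan
    return {
        "shannon": shannon,
        "simpson": simpson,
        "shannon_evenness": shannon / logm if m >= 2 else np.nan,
        "simpson_evenness": simpson / logm if m >= 2 else np.nan,
        "pielou_evenness": shannon / logm if m >= 2 else np.nan,
        "richness": float(m),
    }


def simulate_covariates(p: SimulationParams, metadata: SampleMetadata,
                        rng=None) -> SampleMetadata:
    """Fill coordinates, soil chemistry and vegetation covariates.

    Soil variables are drawn normal around stand-specific means (offsets
    scaled by ``p.covariate_effect``; zero gives covariates independent of
    stand type).  Coordinates are uniform in the configured box and shared
    between the two layers of a quadrat.  Plant importance-value vectors
    are Dirichlet draws with stand-specific preferences; diversity indices
    are computed from them.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([p.seed, 7]))
    frame = metadata.frame.copy()
    quadrats = (
        frame["quadrat"]
        if "quadrat" in frame.columns
        else pd.Series(frame.index, index=frame.index)
    )
    offsets = p.soil_offsets if p.soil_offsets is not None else _SOIL_OFFSETS

    (lon_lo, lon_hi), (lat_lo, lat_hi), (ele_lo, ele_hi) = p.coordinate_box
    per_quadrat: dict[str, dict] = {}
    for q in pd.unique(quadrats):
        mask = quadrats == q
        stand = frame.loc[mask, "stand_type"].iloc[0]
        rec = {
            "longitude_deg": rng.uniform(lon_lo, lon_hi),
            "latitude_deg": rng.uniform(lat_lo, lat_hi),
            "elevation_m": rng.uniform(ele_lo, ele_hi),
        }
        tree = rng.dirichlet(np.asarray(_TREE_PREFS[stand], dtype=float))
        shrub = rng.dirichlet(np.asarray(_SHRUB_PREFS[stand], dtype=float))
        tree_w = 0.0 if stand == "S" else 0.7
        combined = np.concatenate([tree * tree_w, shrub * (1 - tree_w)])
        rec["tree"] = tree if stand != "S" else np.zeros_like(tree)
        rec["shrub"] = shrub
        rec["plantdiv"] = _plant_diversity_indices(combined)
        per_quadrat[q] = rec

    for col in ("longitude_deg", "latitude_deg", "elevation_m"):
        frame[col] = [per_quadrat[q][col] for q in quadrats]
    for k, sp in enumerate(_TREE_SPECIES):
        frame[f"tree_{sp}"] = [per_quadrat[q]["tree"][k] for q in quadrats]
    for k, sp in enumerate(_SHRUB_SPECIES):
        frame[f"shrub_{sp}"] = [per_quadrat[q]["shrub"][k] for q in quadrats]
    for key in ("shannon", "simpson", "shannon_evenness", "simpson_evenness",
                "pielou_evenness", "richness"):
        frame[f"plantdiv_{key}"] = [
            per_quadrat[q]["plantdiv"][key] for q in quadrats
        ]

    for var in _SOIL_VARS:
        mean, sd = _SOIL_BASELINE[var]
        values = []
        for sid in frame.index:
            stand = frame.loc[sid, "stand_type"]
            layer = frame.loc[sid, "soil_layer"]
            mu = mean + p.covariate_effect * sd * offsets.get(stand, {}).get(var, 0.0)
            if layer == "subsoil":
                mu += sd * _SUBSOIL_SHIFT.get(var, 0.0)
            values.append(rng.normal(mu, sd))
        frame[f"soil_{var}"] = values

    return SampleMetadata(frame)
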