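"""Synthetic ASV tables with the statistical structure of a contaminated
low-biomass subsurface drilling survey, plus scoring of decontamination
output against the planted ground truth.

The generator emulates the post-denoising state of such a study: five feature
pools with known origins —

* ``endemic_subaerial`` — residents of the tuff cone above coastal sea level,
* ``endemic_submarine`` — residents of the submarine deposit,
* ``seawater`` — marine taxa present in the sea (and hence in the
  seawater-derived drilling fluid, and naturally infiltrating the deepest
  cores through the seawater-inflow zone),
* ``drillfluid_only`` — taxa that bloomed in the stored drilling fluid but
  are not detectable in the open-sea samples,
* ``reagent`` — kit/laboratory taxa appearing only in negative controls.

Each feature has a fixed lognormal base abundance within its pool; endemic
features additionally carry a Gaussian thermal niche so community composition
turns over along the borehole's depth/temperature gradient.  Drill-core
samples are multinomial draws from a mixture
``(1 - c_j) * endemic profile + c_j * drilling-fluid profile`` with a
per-sample carryover fraction ``c_j ~ Beta(a, b)``; cores below the seawater
inflow zone receive an extra seawater component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .community_stats import bray_curtis
from .decontamination import ContaminantCall
from .tables_io import (
    CoreCategory,
    Dataset,
    FeatureTable,
    SampleRecord,
    SampleType,
    TaxonomyRecord,
    UNASSIGNED,
)

ORIGINS = (
    "endemic_subaerial",
    "endemic_submarine",
    "seawater",
    "drillfluid_only",
    "reagent",
)

#: small illustrative genus blocklist of common reagent/laboratory
#: contaminants (user-editable; real surveys curate their own list)
DEFAULT_BLOCKLIST = (
    "Cutibacterium",
    "Ralstonia",
    "Burkholderia",
    "Sphingomonas",
    "Methylobacterium",
    "Bradyrhizobium",
    "Mesorhizobium",
    "Delftia",
    "Acinetobacter",
    "Corynebacterium",
    "Streptococcus",
    "Staphylococcus",
)

# drill-core sampling design: (core category, depth m below surface, temp °C),
# following the borehole's published depth/temperature profile
DEFAULT_CORE_DESIGN = (
    ("DC_1", 23.0, 20.0),
    ("DC_1", 35.0, 36.0),
    ("DC_2", 44.0, 59.0),
    ("DC_2", 55.0, 82.5),
    ("DC_2", 65.0, 101.5),
    ("DC_3", 78.0, 114.0),
    ("DC_3", 93.0, 123.0),
    ("DC_3", 102.0, 124.0),
    ("DC_3", 111.0, 121.5),
    ("DC_3", 120.0, 116.0),
    ("DC_3", 130.0, 107.0),
    ("DC_3", 139.0, 97.0),
    ("DC_4", 148.0, 84.0),
    ("DC_4", 157.0, 64.0),
    ("DC_4", 166.0, 55.0),
    ("DC_4", 175.0, 44.5),
    ("DC_4", 181.0, 37.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic community generator.

    Feature-pool sizes default to 300 features split so that the
    drilling-fluid bloom dominates the contaminant side (see the methods
    note); sample counts mirror a 51-sample survey: 17 drill cores across
    the four depth categories, 18 borehole fluids, 2 fumaroles, 4 seawater,
    8 drilling fluid, 2 negative controls.
    """

    n_endemic_subaerial: int = 40
    n_endemic_submarine: int = 110
    n_seawater: int = 30
    n_drillfluid_only: int = 90
    n_reagent: int = 30
    core_design: tuple = DEFAULT_CORE_DESIGN
    n_borehole_fluid: int = 18
    n_fumarole: int = 2
    n_seawater_samples: int = 4
    n_drillfluid_samples: int = 8
    n_controls: int = 2
    # lognormal base abundances (per-feature rank within its pool)
    abundance_meanlog: float = 0.0
    abundance_sdlog: float = 1.5
    # Gaussian thermal niche of endemic features
    niche_optimum_range_C: tuple[float, float] = (10.0, 125.0)
    niche_width_C: float = 25.0
    # drilling-fluid carryover fraction per drill core, c_j ~ Beta(a, b)
    contamination_beta_a: float = 2.0
    contamination_beta_b: float = 6.0
    # extra seawater mass in cores below the inflow zone (DC_4)
    seawater_inflow_fraction: float = 0.10
    # library sizes N_j ~ LogNormal(ln 30000, 0.3)
    library_meanlog: float = float(np.log(30000.0))
    library_sdlog: float = 0.3
    # planted taxonomy-screen targets
    blocklisted_genus_fraction: float = 0.05  # of reagent features
    chloroplast_fraction: float = 0.02  # of all features
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_endemic_subaerial", "n_endemic_submarine", "n_seawater",
            "n_drillfluid_only", "n_reagent", "n_borehole_fluid", "n_fumarole",
            "n_seawater_samples", "n_drillfluid_samples", "n_controls",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.contamination_beta_a <= 0 or self.contamination_beta_b <= 0:
            raise ValueError("Beta parameters must be strictly positive")
        if self.library_sdlog <= 0:
            raise ValueError("library sdlog must be strictly positive")
        if self.niche_width_C <= 0:
            raise ValueError("niche width must be strictly positive")

    @property
    def n_features(self) -> int:
        return (
            self.n_endemic_subaerial + self.n_endemic_submarine + self.n_seawater
            + self.n_drillfluid_only + self.n_reagent
        )


@dataclass
class GroundTruth:
    """Planted origins and mixing fractions emitted alongside the table."""

    origins: dict[str, str]  # feature_id -> origin label
    contamination_fraction: dict[str, float]  # drill-core sample -> c_j
    library_sizes: dict[str, int]  # sample -> N_j
    expected_endemic: dict[str, np.ndarray] = field(default_factory=dict)
    feature_ids: list[str] = field(default_factory=list)

    def features_of_origin(self, *origins: str) -> set[str]:
        wanted = set(origins)
        return {f for f, o in self.origins.items() if o in wanted}


@dataclass(frozen=True)
class ConfusionMetrics:
    true_positive: int
    false_positive: int
    false_negative: int
    true_negative: int
    precision: float
    recall: float
    f1: float
    precision_undefined: bool = False


def niche_weight(temperature_C: float, optimum_C: float, width_C: float) -> float:
    """Gaussian thermal-niche weight, exp(-(T - T_opt)^2 / (2 sigma^2))."""
    if width_C <= 0:
        raise ValueError("niche width must be strictly positive")
    if not np.isfinite(temperature_C):
        raise ValueError("temperature must be finite")
    return float(np.exp(-((temperature_C - optimum_C) ** 2) / (2.0 * width_C**2)))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _lineage(i: int, kingdom="Bacteria", phylum=None, genus=None, order=None):
    phylum = phylum or f"Phylum{i % 12}"
    return dict(
        kingdom=kingdom,
        phylum=phylum,
        class_=f"Class{i % 25}",
        order=order or f"Order{i % 40}",
        family=f"Family{i % 60}",
        genus=genus or f"Genus{i % 90}",
        species=UNASSIGNED,
    )


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Draw one synthetic dataset plus its ground truth.

    Deterministic under ``config.seed`` (bit-for-bit identical output).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    if n == 0:
        raise ValueError("empty pool with nonzero requested mass")
    width = len(str(n))
    feature_ids = [f"ASV{str(i + 1).zfill(width)}" for i in range(n)]

    origins: list[str] = (
        ["endemic_subaerial"] * config.n_endemic_subaerial
        + ["endemic_submarine"] * config.n_endemic_submarine
        + ["seawater"] * config.n_seawater
        + ["drillfluid_only"] * config.n_drillfluid_only
        + ["reagent"] * config.n_reagent
    )
    origin_arr = np.array(origins)

    base = rng.lognormal(config.abundance_meanlog, config.abundance_sdlog, size=n)
    lo, hi = config.niche_optimum_range_C
    t_opt = rng.uniform(lo, hi, size=n)

    def pool_mask(*names: str) -> np.ndarray:
        return np.isin(origin_arr, names)

    endemic_sub_a = pool_mask("endemic_subaerial")
    endemic_sub_m = pool_mask("endemic_submarine")
    sw_mask = pool_mask("seawater")
    df_only_mask = pool_mask("drillfluid_only")
    reagent_mask = pool_mask("reagent")

    def normalized(weights: np.ndarray) -> np.ndarray:
        total = weights.sum()
        if total <= 0:
            raise ValueError("empty pool with nonzero requested mass")
        return weights / total

    def endemic_profile(mask: np.ndarray, temperature: float) -> np.ndarray:
        w = np.zeros(n)
        w[mask] = base[mask] * np.exp(
            -((temperature - t_opt[mask]) ** 2) / (2.0 * config.niche_width_C**2)
        )
        if w.sum() <= 0:  # pathologically narrow niche: fall back on base ranks
            w[mask] = base[mask]
        return normalized(w)

    sw_profile = normalized(np.where(sw_mask, base, 0.0)) if sw_mask.any() else None
    df_pool = sw_mask | df_only_mask
    df_profile = normalized(np.where(df_pool, base, 0.0)) if df_pool.any() else None
    reagent_profile = (
        normalized(np.where(reagent_mask, base, 0.0)) if reagent_mask.any() else None
    )

    # ---- sample frame ----------------------------------------------------
    samples: list[SampleRecord] = []
    for k, (cat, depth, temp) in enumerate(config.core_design, start=1):
        samples.append(SampleRecord(
            f"C{k:02d}", SampleType.DRILL_CORE, CoreCategory(cat), depth, temp))
    bf_depths = np.linspace(58, 166, max(config.n_borehole_fluid, 1))
    for k in range(config.n_borehole_fluid):
        d = float(bf_depths[k])
        # crude mirror of the borehole's thermal bulge around ~100 m
        temp = 125.0 - 0.9 * abs(d - 100.0)
        samples.append(SampleRecord(
            f"BF{k + 1:02d}", SampleType.BOREHOLE_FLUID, depth_m=d, temperature_C=temp))
    for k in range(config.n_fumarole):
        samples.append(SampleRecord(
            f"FUM{k + 1}", SampleType.FUMAROLE, depth_m=0.0, temperature_C=82.0 + 3.0 * k))
    for k in range(config.n_seawater_samples):
        samples.append(SampleRecord(
            f"SW{k + 1:02d}", SampleType.SEAWATER, depth_m=10.0 * (k + 1),
            temperature_C=12.0 - 0.5 * k))
    for k in range(config.n_drillfluid_samples):
        samples.append(SampleRecord(f"DF{k + 1:02d}", SampleType.DRILLING_FLUID,
                                    depth_m=1.0, temperature_C=10.0))
    for k in range(config.n_controls):
        samples.append(SampleRecord(f"NEG{k + 1}", SampleType.NEGATIVE_CONTROL,
                                    is_control=True))

    core_ids = [s.sample_id for s in samples if s.sample_type == SampleType.DRILL_CORE]
    c_j = dict(zip(
        core_ids,
        rng.beta(config.contamination_beta_a, config.contamination_beta_b,
                 size=len(core_ids)),
    ))
    lib = rng.lognormal(config.library_meanlog, config.library_sdlog, size=len(samples))
    library_sizes = {
        s.sample_id: max(1, int(round(L))) for s, L in zip(samples, lib)
    }

    expected_endemic: dict[str, np.ndarray] = {}
    counts = np.zeros((n, len(samples)), dtype=np.int64)
    for j, rec in enumerate(samples):
        if rec.sample_type == SampleType.DRILL_CORE:
            subaerial = rec.depth_m is not None and rec.depth_m < 58.0
            mask = endemic_sub_a if subaerial else endemic_sub_m
            endemic = endemic_profile(mask, rec.temperature_C)
            expected_endemic[rec.sample_id] = endemic
            c = c_j[rec.sample_id]
            if df_profile is None and c > 0:
                raise ValueError("empty pool with nonzero requested mass")
            profile = (1.0 - c) * endemic + (c * df_profile if df_profile is not None else 0.0)
            if rec.core_category == CoreCategory.DC_4 and sw_profile is not None:
                f_in = config.seawater_inflow_fraction
                profile = (1.0 - f_in) * profile + f_in * sw_profile
        elif rec.sample_type == SampleType.BOREHOLE_FLUID:
            profile = endemic_profile(endemic_sub_m, rec.temperature_C)
        elif rec.sample_type == SampleType.FUMAROLE:
            profile = endemic_profile(endemic_sub_a, rec.temperature_C)
        elif rec.sample_type == SampleType.SEAWATER:
            if sw_profile is None:
                raise ValueError("empty pool with nonzero requested mass")
            profile = sw_profile
        elif rec.sample_type == SampleType.DRILLING_FLUID:
            if df_profile is None:
                raise ValueError("empty pool with nonzero requested mass")
            profile = df_profile
        else:  # negative control
            if reagent_profile is None:
                raise ValueError("empty pool with nonzero requested mass")
            profile = reagent_profile
        profile = profile / profile.sum()
        counts[:, j] = rng.multinomial(library_sizes[rec.sample_id], profile)

    table = FeatureTable(pd.DataFrame(
        counts, index=feature_ids, columns=[s.sample_id for s in samples]))

    # ---- taxonomy with planted screen targets ----------------------------
    n_block = len(DEFAULT_BLOCKLIST)
    blocked = rng.random(n) < np.where(reagent_mask, config.blocklisted_genus_fraction, 0.0)
    chloro = rng.random(n) < config.chloroplast_fraction
    taxonomy: dict[str, TaxonomyRecord] = {}
    for i, fid in enumerate(feature_ids):
        kw = _lineage(i)
        if origin_arr[i] == "seawater":
            kw["phylum"] = "Proteobacteria"
        if blocked[i]:
            kw["genus"] = DEFAULT_BLOCKLIST[i % n_block]
        if chloro[i]:
            kw["kingdom"] = "Bacteria"
            kw["phylum"] = "Cyanobacteria"
            kw["order"] = "Chloroplast"
        taxonomy[fid] = TaxonomyRecord(fid, **kw)

    dataset = Dataset(
        table=table,
        metadata={s.sample_id: s for s in samples},
        taxonomy=taxonomy,
    )
    truth = GroundTruth(
        origins=dict(zip(feature_ids, origins)),
        contamination_fraction=c_j,
        library_sizes=library_sizes,
        expected_endemic=expected_endemic,
        feature_ids=feature_ids,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def evaluate_calls(
    calls: Iterable[ContaminantCall],
    truth: GroundTruth,
    positive_origins: Iterable[str] = ("drillfluid_only", "reagent"),
) -> ConfusionMetrics:
    """Confusion metrics of the cascade's remove-set against the planted
    origins.  A feature is predicted positive iff any call removes it."""
    positive_origins = set(positive_origins)
    unknown = positive_origins - set(ORIGINS)
    if unknown:
        raise ValueError(f"unknown origin label(s): {sorted(unknown)}")
    known = set(truth.origins)
    predicted: set[str] = set()
    for call in calls:
        if call.feature_id not in known:
            raise ValueError(f"call for unknown feature {call.feature_id!r}")
        if call.verdict == "remove":
            predicted.add(call.feature_id)
    actual = truth.features_of_origin(*positive_origins)
    tp = len(predicted & actual)
    fp = len(predicted - actual)
    fn = len(actual - predicted)
    tn = len(known) - tp - fp - fn
    undefined = (tp + fp) == 0
    precision = 0.0 if undefined else tp / (tp + fp)
    recall = 0.0 if not actual else tp / (tp + fn)
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return ConfusionMetrics(tp, fp, fn, tn, precision, recall, f1,
                            precision_undefined=undefined)


def composition_error(
    cleaned: FeatureTable, truth: GroundTruth, config: SimulationConfig | None = None
) -> float:
    """Mean Bray-Curtis distance between each drill-core sample's observed
    relative-abundance vector (over the features present in ``cleaned``) and
    its true expected endemic profile."""
    unknown = [s for s in cleaned.sample_ids if s not in truth.library_sizes]
    if unknown:
        raise ValueError(f"sample {unknown[0]!r} absent from truth")
    core_samples = [s for s in cleaned.sample_ids if s in truth.expected_endemic]
    if not core_samples:
        raise ValueError("no drill-core sample of the truth present in the table")
    index = {f: i for i, f in enumerate(truth.feature_ids)}
    rows = [index[f] for f in cleaned.feature_ids if f in index]
    if len(rows) != cleaned.shape[0]:
        raise ValueError("cleaned table contains features unknown to the truth")
    dists = []
    for s in core_samples:
        obs_full = np.zeros(len(truth.feature_ids))
        obs_full[rows] = cleaned.sample(s)
        if obs_full.sum() == 0:
            continue
        obs = obs_full / obs_full.sum()
        dists.append(bray_curtis(obs, truth.expected_endemic[s]))
    if not dists:
        raise ValueError("no non-empty drill-core sample to score")
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# incidence fixtures for the overlap classifier
# ---------------------------------------------------------------------------

def incidence_table_from_census(
    region_counts: Mapping[str, int], prefix: str = "V"
) -> tuple[FeatureTable, dict[str, list[str]]]:
    """Build a minimal presence/absence feature table whose Venn-region
    occupancies equal ``region_counts``.

    Keys are region labels like ``"SUB_A+DF"`` (group names joined by ``+``
    in the order SUB_A, SUB_M, DF, SW).  One sample per group; each feature
    gets count 1 in every group of its region.  Returns the table and the
    group map for :func:`tephraseq.decontamination.presence_pattern`.
    """
    from .decontamination import GROUPS  # local import to avoid cycle at import time

    group_samples = {g: f"{g}_1" for g in GROUPS}
    rows = []
    ids = []
    k = 0
    for region, count in region_counts.items():
        members = region.split("+")
        unknown = set(members) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group(s) in region {region!r}: {sorted(unknown)}")
        for _ in range(int(count)):
            k += 1
            ids.append(f"{prefix}{k:04d}")
            rows.append([1 if g in members else 0 for g in GROUPS])
    table = FeatureTable(pd.DataFrame(
        np.array(rows, dtype=np.int64).reshape(len(ids), len(GROUPS)),
        index=ids, columns=[group_samples[g] for g in GROUPS]))
    groups = {g: [group_samples[g]] for g in GROUPS}
    return table, groups
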