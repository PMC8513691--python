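"""Three-stage contaminant identification cascade for low-biomass amplicon data.

Drilling into a low-biomass subsurface habitat with (nominally sterilized)
seawater as drilling fluid introduces marine taxa into the cores, and kit
reagents introduce their own taxa into every extraction.  The cascade
identifies contaminant features in three complementary ways:

1. **Prevalence test** — a feature more prevalent in negative controls than in
   true samples is a reagent/laboratory contaminant (two-sided chi-square on
   the 2x2 presence table, Fisher's exact test when expected cells are small,
   removal only in the control-enriched direction, score threshold 0.5).
2. **Taxonomy screen** — chloroplast (order), mitochondria (family), eukaryote
   or unassigned kingdom, and a user-editable genus blocklist of known
   reagent contaminants.
3. **Overlap classifier** — a geologically informed four-set rule over the
   presence pattern of each feature across subaerial drill cores (SUB_A),
   submarine drill cores (SUB_M), drilling fluid (DF) and seawater (SW).
   The subaerial deposit sits above coastal sea level and should hold no
   marine taxa, so anything shared between subaerial cores and drilling
   fluid or seawater is a marine contaminant (R1); features shared only
   between submarine cores and drilling fluid were carried downhole by the
   fluid (R2, removed); features shared between submarine cores, drilling
   fluid *and* seawater may derive from the natural seawater inflow into the
   deep submarine deposit and are retained (R3).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import (
    UNASSIGNED,
    Dataset,
    FeatureTable,
    SampleRecord,
    SampleType,
    TaxonomyRecord,
)

GROUPS = ("SUB_A", "SUB_M", "DF", "SW")

RULE_R1 = "R1_subaerial_marine"
RULE_R2 = "R2_drillfluid_only"
RULE_R3 = "R3_inflow_retained"
RULE_ENDEMIC = "endemic_candidate"


@dataclass(frozen=True)
class ContaminantCall:
    """Per-feature verdict from one cascade stage."""

    feature_id: str
    stage: str  # prevalence | taxonomy | overlap
    verdict: str  # remove | retain
    rule: str
    evidence: str = ""
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.verdict not in {"remove", "retain"}:
            raise ValueError(f"unknown verdict {self.verdict!r}")


@dataclass(frozen=True)
class PresencePattern:
    """Presence flags of one feature across the four overlap groups."""

    present_subaerial: bool
    present_submarine: bool
    present_drillfluid: bool
    present_seawater: bool

    def as_tuple(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.present_subaerial,
            self.present_submarine,
            self.present_drillfluid,
            self.present_seawater,
        )

    def region(self) -> str:
        """Canonical label of the Venn region this pattern occupies."""
        names = [g for g, f in zip(GROUPS, self.as_tuple()) if f]
        return "+".join(names) if names else "none"

    @property
    def any_presence(self) -> bool:
        return any(self.as_tuple())


# ---------------------------------------------------------------------------
# stage 1: prevalence test against negative controls
# ---------------------------------------------------------------------------

def _prevalence_p_value(
    present_true: int, n_true: int, present_ctrl: int, n_ctrl: int
) -> tuple[float, str]:
    """Two-sided p for the 2x2 [present, absent] x [true, control] table.

    Chi-square without continuity correction; Fisher's exact test whenever
    any expected cell count is below 5.
    """
    table = np.array(
        [
            [present_true, n_true - present_true],
            [present_ctrl, n_ctrl - present_ctrl],
        ],
        dtype=float,
    )
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    if total == 0 or 0 in row or 0 in col:
        return 1.0, "degenerate"
    expected = np.outer(row, col) / total
    if (expected < 5).any():
        _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
        return float(p), "fisher"
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1)), "chi2"


def prevalence_contaminant_test(
    table: FeatureTable,
    metadata: Mapping[str, SampleRecord],
    threshold: float = 0.5,
    min_count: int = 1,
    n_true_min: int = 2,
) -> list[ContaminantCall]:
    """Flag features whose presence is more prevalent in negative controls.

    A feature is "present" in a sample when its count is >= ``min_count``.
    Features absent from every control are retained without testing.  The
    remove verdict requires both p < ``threshold`` and a control prevalence
    fraction strictly above the true-sample prevalence fraction.
    """
    controls = [s for s in table.sample_ids if metadata[s].is_control]
    true_samples = [s for s in table.sample_ids if not metadata[s].is_control]
    if not controls:
        raise ValueError("prevalence method requires negative controls")
    if len(true_samples) < n_true_min:
        raise ValueError(
            f"prevalence method requires at least {n_true_min} true samples "
            f"(got {len(true_samples)})"
        )
    df = table.to_dataframe()
    present = df >= min_count
    pt = present[true_samples].sum(axis=1)
    pc = present[controls].sum(axis=1)
    n_t, n_c = len(true_samples), len(controls)
    calls: list[ContaminantCall] = []
    for fid in table.feature_ids:
        a, b = int(pt[fid]), int(pc[fid])
        if b == 0:
            calls.append(
                ContaminantCall(fid, "prevalence", "retain", "prevalence_p",
                                evidence="absent_from_controls")
            )
            continue
        p, method = _prevalence_p_value(a, n_t, b, n_c)
        control_enriched = (b / n_c) > (a / n_t)
        verdict = "remove" if (p < threshold and control_enriched) else "retain"
        calls.append(
            ContaminantCall(
                fid, "prevalence", verdict, "prevalence_p",
                evidence=f"{method}:{a}/{n_t}|{b}/{n_c}", p_value=p,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# stage 2: taxonomy screen
# ---------------------------------------------------------------------------

def taxonomy_screen(
    taxonomy: Mapping[str, TaxonomyRecord],
    blocklist_genera: Iterable[str] = (),
) -> list[ContaminantCall]:
    """Remove organellar, eukaryotic, kingdom-unassigned and blocklisted taxa.

    Rules: order == Chloroplast, family == Mitochondria, kingdom == Eukaryota,
    kingdom UNASSIGNED, or genus in the blocklist (case-insensitive exact
    match).  One call per matched rule.
    """
    block = {g.strip().lower() for g in blocklist_genera if g.strip()}
    calls: list[ContaminantCall] = []
    for fid, rec in taxonomy.items():
        if rec.order.lower() == "chloroplast":
            calls.append(ContaminantCall(fid, "taxonomy", "remove", "chloroplast",
                                         evidence=f"order={rec.order}"))
        if rec.family.lower() == "mitochondria":
            calls.append(ContaminantCall(fid, "taxonomy", "remove", "mitochondria",
                                         evidence=f"family={rec.family}"))
        if rec.kingdom.lower() in {"eukaryota", "eukaryote"}:
            calls.append(ContaminantCall(fid, "taxonomy", "remove", "eukaryote",
                                         evidence=f"kingdom={rec.kingdom}"))
        if rec.kingdom == UNASSIGNED:
            calls.append(ContaminantCall(fid, "taxonomy", "remove", "unassigned_kingdom"))
        if rec.genus != UNASSIGNED and rec.genus.lower() in block:
            calls.append(ContaminantCall(fid, "taxonomy", "remove", "genus_blocklist",
                                         evidence=f"genus={rec.genus}"))
    return calls


# ---------------------------------------------------------------------------
# stage 3: overlap classifier
# ---------------------------------------------------------------------------

def presence_pattern(
    table: FeatureTable,
    groups: Mapping[str, Sequence[str]],
    min_count: int = 1,
) -> dict[str, PresencePattern]:
    """Presence flags per feature over the four overlap groups.

    ``groups`` maps each group name in :data:`GROUPS` to its sample ids; a
    sample may belong to at most one group.  A flag is true iff the feature
    has count >= ``min_count`` in at least one sample of the group.
    """
    unknown = set(groups) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group name(s): {sorted(unknown)}")
    seen: dict[str, str] = {}
    for g, samples in groups.items():
        for s in samples:
            if s in seen:
                raise ValueError(f"sample {s!r} assigned to both {seen[s]!r} and {g!r}")
            if s not in table.sample_ids:
                raise ValueError(f"sample {s!r} not in table")
            seen[s] = g
    df = table.to_dataframe()
    flags = {}
    for g in GROUPS:
        members = list(groups.get(g, ()))
        if members:
            flags[g] = (df[members] >= min_count).any(axis=1)
        else:
            flags[g] = pd.Series(False, index=df.index)
    return {
        fid: PresencePattern(
            bool(flags["SUB_A"][fid]),
            bool(flags["SUB_M"][fid]),
            bool(flags["DF"][fid]),
            bool(flags["SW"][fid]),
        )
        for fid in table.feature_ids
    }


def classify_pattern(pattern: PresencePattern) -> str:
    """Rule label of one presence pattern, evaluated in priority order
    R1 > R3 > R2 > endemic_candidate."""
    sub_a, sub_m, df, sw = pattern.as_tuple()
    if sub_a and (df or sw):
        return RULE_R1
    if sub_m and df and sw:
        return RULE_R3
    if sub_m and df:
        return RULE_R2
    return RULE_ENDEMIC


def overlap_classify(patterns: Mapping[str, PresencePattern]) -> dict[str, str]:
    """Apply :func:`classify_pattern` to every feature."""
    return {fid: classify_pattern(p) for fid, p in patterns.items()}


def overlap_calls(patterns: Mapping[str, PresencePattern]) -> list[ContaminantCall]:
    """Contaminant calls from the overlap classifier (R1/R2 remove, R3
    retain; endemic candidates produce no call)."""
    calls = []
    for fid, pattern in patterns.items():
        rule = classify_pattern(pattern)
        if rule in (RULE_R1, RULE_R2):
            calls.append(ContaminantCall(fid, "overlap", "remove", rule,
                                         evidence=pattern.region()))
        elif rule == RULE_R3:
            calls.append(ContaminantCall(fid, "overlap", "retain", rule,
                                         evidence=pattern.region()))
    return calls


def venn_census(patterns: Mapping[str, PresencePattern]) -> dict[str, int]:
    """Feature count per non-empty Venn region (15 regions); features with no
    presence anywhere are tallied under ``"none"``."""
    census: Counter[str] = Counter()
    for pattern in patterns.values():
        census[pattern.region()] += 1
    out = {}
    for mask in range(1, 16):
        flags = tuple(bool(mask & (1 << i)) for i in range(4))
        region = PresencePattern(*flags).region()
        out[region] = census.get(region, 0)
    out["none"] = census.get("none", 0)
    return out


# ---------------------------------------------------------------------------
# applying calls
# ---------------------------------------------------------------------------

@dataclass
class CleaningReport:
    """Bookkeeping from :func:`apply_calls`."""

    removed_features: list[str]
    dropped_samples: list[str]
    removed_reads_per_sample: dict[str, int]
    removed_fraction_per_sample: dict[str, float]


def apply_calls(
    dataset: Dataset,
    calls: Iterable[ContaminantCall],
    drop_sample_types: Iterable[SampleType] = (
        SampleType.DRILLING_FLUID,
        SampleType.NEGATIVE_CONTROL,
    ),
) -> tuple[Dataset, CleaningReport]:
    """Delete every feature with a remove verdict (whole rows) and drop the
    given sample types; report removed-read totals per remaining sample."""
    known = set(dataset.table.feature_ids)
    remove: set[str] = set()
    for call in calls:
        if call.feature_id not in known:
            raise ValueError(f"call references unknown feature {call.feature_id!r}")
        if call.verdict == "remove":
            remove.add(call.feature_id)
    drop_types = set(drop_sample_types)
    dropped = [
        s for s in dataset.table.sample_ids
        if dataset.metadata[s].sample_type in drop_types
    ]
    table = dataset.table.drop_samples(dropped)
    before = table.column_sums()
    cleaned = table.drop_features(remove)
    if cleaned.shape[0] == 0:
        raise ValueError("all features removed")
    after = cleaned.column_sums()
    removed_reads = {s: int(before[s] - after[s]) for s in cleaned.sample_ids}
    removed_frac = {
        s: (removed_reads[s] / before[s] if before[s] > 0 else 0.0)
        for s in cleaned.sample_ids
    }
    out = Dataset(
        table=cleaned,
        metadata={s: dataset.metadata[s] for s in cleaned.sample_ids},
        taxonomy={f: dataset.taxonomy[f] for f in cleaned.feature_ids},
    )
    return out, CleaningReport(
        removed_features=[f for f in dataset.table.feature_ids if f in remove],
        dropped_samples=dropped,
        removed_reads_per_sample=removed_reads,
        removed_fraction_per_sample=removed_frac,
    )


def default_overlap_groups(
    metadata: Mapping[str, SampleRecord],
    subaerial_max_depth_m: float = 58.0,
) -> dict[str, list[str]]:
    """Default group map for the overlap classifier.

    Drill cores shallower than the tidal-flux zone (~58 m below surface, the
    top of the submarine deposit) count as subaerial; deeper cores as
    submarine.  Drilling-fluid and seawater samples map to DF and SW.  Cores
    with missing depth fall back on the core category (DC_1 subaerial,
    DC_3/DC_4 submarine; DC_2 straddles the boundary and defaults to
    subaerial, matching the four-sample subaerial group of the study design).
    """
    groups: dict[str, list[str]] = {g: [] for g in GROUPS}
    for sid, rec in metadata.items():
        if rec.sample_type == SampleType.DRILL_CORE:
            if rec.depth_m is not None:
                key = "SUB_A" if rec.depth_m < subaerial_max_depth_m else "SUB_M"
            else:
                key = "SUB_A" if rec.core_category.value in {"DC_1", "DC_2"} else "SUB_M"
            groups[key].append(sid)
        elif rec.sample_type == SampleType.DRILLING_FLUID:
            groups["DF"].append(sid)
        elif rec.sample_type == SampleType.SEAWATER:
            groups["SW"].append(sid)
    return groups


def run_cascade(
    dataset: Dataset,
    blocklist_genera: Iterable[str] = (),
    groups: Mapping[str, Sequence[str]] | None = None,
    threshold: float = 0.5,
    min_count: int = 1,
) -> tuple[list[ContaminantCall], dict[str, PresencePattern]]:
    """Run all three stages on a dataset and return the combined call list
    plus the overlap presence patterns (for census reporting)."""
    calls = prevalence_contaminant_test(
        dataset.table, dataset.metadata, threshold=threshold, min_count=min_count
    )
    calls += taxonomy_screen(dataset.taxonomy, blocklist_genera)
    if groups is None:
        groups = default_overlap_groups(dataset.metadata)
    patterns = presence_pattern(dataset.table, groups, min_count=min_count)
    calls += overlap_calls(patterns)
    return calls, patterns
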