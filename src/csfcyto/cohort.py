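"""Cohort configuration: per-diagnosis-group generative parameters.

Seven diagnosis groups are supported: NIND (non-inflammatory controls),
PIND (peripheral inflammatory), AIE (autoimmune encephalitis), IDWM
(inherited white-matter disorders), otherADS, MOGAD and MS.  The NIND group
is anchored on published cohort medians (leukocyte composition, T subsets,
memory fractions, cell concentration); the inflammatory groups carry
direction-constrained defaults: higher cellularity than NIND, strong B-cell
enrichment in all demyelinating (ADS) groups, and an MS profile with high
antibody-secreting-cell (ASC) content, depressed CD14+ myeloid frequency and
near-absent granulocytes relative to MOGAD / other ADS.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .panel import ExpressionModel, MarkerPanel

GROUP_LABELS = ("NIND", "PIND", "AIE", "IDWM", "otherADS", "MOGAD", "MS")

LINEAGES = ("T", "CD14myeloid", "NK", "DC", "B", "PMN", "unassigned")

_PARTITION_TOL = 1e-9


def _check_partition(name: str, parts: dict[str, float]) -> None:
    for key, value in parts.items():
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name}[{key}] = {value} is outside [0, 1]")
    total = sum(parts.values())
    if abs(total - 1.0) > _PARTITION_TOL:
        raise ValueError(f"{name} must sum to 1 (got {total!r})")


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} = {value} is outside [0, 1]")


@dataclass
class GroupSpec:
    """Generative parameters for one diagnosis group."""

    label: str
    n_donors: int
    age_range: tuple[float, float]
    conc_median: float            # cells/uL, lognormal median
    conc_log_sd: float            # sd on the natural-log scale
    composition: dict[str, float]  # over LINEAGES, sums to 1
    t_subsets: dict[str, float] = field(
        default_factory=lambda: {"CD4": 0.672, "CD8": 0.236, "DN": 0.084, "DP": 0.008})
    cd4_memory_fraction: float = 0.978
    cd4_memory_states: dict[str, float] = field(
        default_factory=lambda: {"CM": 0.80, "EM": 0.18, "TEMRA": 0.02})
    cd8_memory_states: dict[str, float] = field(
        default_factory=lambda: {"CM": 0.55, "EM": 0.35, "TEMRA": 0.10})
    th_states: dict[str, float] = field(
        default_factory=lambda: {"Th1": 0.60, "Th17": 0.15, "Th1_17": 0.10, "Th_DN": 0.15})
    cd4_activated_fraction: float = 0.02
    cd8_activated_fraction: float = 0.05
    treg_fraction: float = 0.05
    nkt_fraction: float = 0.05
    asc_fraction: float = 0.02
    asc_zero_inflation: float = 0.0
    # (intercept, slope per year, lower clamp, upper clamp) for the naive-CD8
    # fraction as a decreasing linear function of age
    naive_cd8_model: tuple[float, float, float, float] = (0.74, 0.0467, 0.02, 0.95)

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if self.conc_median <= 0:
            raise ValueError("concentration median must be positive")
        if self.conc_log_sd < 0:
            raise ValueError("concentration log-sd must be non-negative")
        lo, hi = self.age_range
        if not (0 <= lo <= hi):
            raise ValueError(f"invalid age range {self.age_range}")
        if set(self.composition) != set(LINEAGES):
            raise ValueError(f"composition must cover exactly {LINEAGES}")
        _check_partition("composition", self.composition)
        _check_partition("t_subsets", self.t_subsets)
        _check_partition("cd4_memory_states", self.cd4_memory_states)
        _check_partition("cd8_memory_states", self.cd8_memory_states)
        _check_partition("th_states", self.th_states)
        for name in ("cd4_memory_fraction", "cd4_activated_fraction",
                     "cd8_activated_fraction", "treg_fraction", "nkt_fraction",
                     "asc_fraction", "asc_zero_inflation"):
            _check_fraction(name, getattr(self, name))
        intercept, slope, clamp_lo, clamp_hi = self.naive_cd8_model
        if clamp_lo > clamp_hi:
            raise ValueError("naive-CD8 clamp bounds out of order")


@dataclass
class CohortConfig:
    """Full generative configuration for a synthetic cohort."""

    groups: list[GroupSpec]
    panel: MarkerPanel = field(default_factory=MarkerPanel)
    expression: ExpressionModel = field(default_factory=ExpressionModel)
    volume_ml: float = 3.0
    event_clamp: tuple[int, int] = (200, 50_000)
    master_seed: int = 1
    # Dirichlet total concentration for donor-level composition jitter;
    # None disables jitter (donor composition == group composition).
    composition_jitter: float | None = 200.0

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("simulated volume must be positive")
        lo, hi = self.event_clamp
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid event-count clamp {self.event_clamp}")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        if self.composition_jitter is not None and self.composition_jitter <= 0:
            raise ValueError("composition jitter concentration must be positive")

    def group(self, label: str) -> GroupSpec:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(f"group {label!r} not present in config")


@dataclass
class DonorRecord:
    """Per-donor metadata mirroring a clinical cohort table."""

    donor_id: str
    group: str
    age: float              # years
    sex: str                # "M" / "F"
    concentration: float    # cells/uL from the (simulated) hemocytometer count
    treated: bool
    volume_ml: float

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


def _remainder(parts: dict[str, float]) -> dict[str, float]:
    parts = dict(parts)
    parts["unassigned"] = round(1.0 - sum(parts.values()), 12)
    return parts


# Default per-group generative parameters.  NIND composition equals the
# published cohort medians with the remainder absorbed by an `unassigned`
# CD45+lineage-negative pool; the other groups are direction-constrained.
_GROUP_DEFAULTS: dict[str, dict[str, Any]] = {
    "NIND": dict(
        n_donors=33, age_range=(2.6, 19.4), conc_median=0.63, conc_log_sd=0.9,
        composition=_remainder({"T": 0.673, "CD14myeloid": 0.129, "NK": 0.043,
                                "DC": 0.016, "B": 0.006, "PMN": 0.003}),
        asc_fraction=0.02),
    "PIND": dict(
        n_donors=7, age_range=(3.5, 19.4), conc_median=0.8, conc_log_sd=0.5,
        composition=_remainder({"T": 0.65, "CD14myeloid": 0.15, "NK": 0.04,
                                "DC": 0.015, "B": 0.010, "PMN": 0.005}),
        asc_fraction=0.02),
    "AIE": dict(
        n_donors=6, age_range=(8.7, 19.0), conc_median=1.2, conc_log_sd=0.5,
        composition=_remainder({"T": 0.68, "CD14myeloid": 0.12, "NK": 0.04,
                                "DC": 0.015, "B": 0.015, "PMN": 0.005}),
        asc_fraction=0.03),
    "IDWM": dict(
        n_donors=4, age_range=(1.3, 17.2), conc_median=0.7, conc_log_sd=0.5,
        composition=_remainder({"T": 0.60, "CD14myeloid": 0.18, "NK": 0.04,
                                "DC": 0.015, "B": 0.008, "PMN": 0.005}),
        asc_fraction=0.02),
    "otherADS": dict(
        n_donors=10, age_range=(0.7, 17.9), conc_median=4.0, conc_log_sd=0.5,
        composition=_remainder({"T": 0.55, "CD14myeloid": 0.22, "NK": 0.04,
                                "DC": 0.015, "B": 0.040, "PMN": 0.030}),
        asc_fraction=0.10, asc_zero_inflation=0.5),
    "MOGAD": dict(
        n_donors=10, age_range=(1.8, 16.2), conc_median=5.0, conc_log_sd=0.5,
        composition=_remainder({"T": 0.52, "CD14myeloid": 0.24, "NK": 0.04,
                                "DC": 0.015, "B": 0.040, "PMN": 0.035}),
        asc_fraction=0.10, asc_zero_inflation=0.5),
    "MS": dict(
        n_donors=15, age_range=(11.6, 19.1), conc_median=3.0, conc_log_sd=0.5,
        composition=_remainder({"T": 0.66, "CD14myeloid": 0.05, "NK": 0.04,
                                "DC": 0.015, "B": 0.120, "PMN": 0.002}),
        asc_fraction=0.12, asc_zero_inflation=0.0),
}


def build_default_config(groups_requested: list[str] | None = None,
                         master_seed: int = 1) -> CohortConfig:
    """Return the built-in CohortConfig restricted to the requested groups.

    With ``groups_requested=None`` all seven groups are included in canonical
    order; an empty list yields a valid config shell with no groups.
    Unknown labels are rejected by name.
    """
    if groups_requested is None:
        groups_requested = list(GROUP_LABELS)
    for label in groups_requested:
        if label not in _GROUP_DEFAULTS:
            raise ValueError(f"unknown diagnosis group label: {label!r}")
    groups = [GroupSpec(label=label, **_GROUP_DEFAULTS[label])
              for label in groups_requested]
    return CohortConfig(groups=groups, master_seed=master_seed)


# ---------------------------------------------------------------------------
# YAML round-trip


def config_to_dict(config: CohortConfig) -> dict[str, Any]:
    d = {
        "panel": list(config.panel.channels),
        "expression": dataclasses.asdict(config.expression),
        "volume_ml": config.volume_ml,
        "event_clamp": list(config.event_clamp),
        "master_seed": config.master_seed,
        "composition_jitter": config.composition_jitter,
        "groups": [],
    }
    for g in config.groups:
        gd = dataclasses.asdict(g)
        gd["age_range"] = list(g.age_range)
        gd["naive_cd8_model"] = list(g.naive_cd8_model)
        d["groups"].append(gd)
    return d


def config_from_dict(d: dict[str, Any]) -> CohortConfig:
    groups = []
    for gd in d.get("groups", []):
        gd = dict(gd)
        gd["age_range"] = tuple(gd["age_range"])
        gd["naive_cd8_model"] = tuple(gd["naive_cd8_model"])
        groups.append(GroupSpec(**gd))
    return CohortConfig(
        groups=groups,
        panel=MarkerPanel(tuple(d["panel"])) if "panel" in d else MarkerPanel(),
        expression=ExpressionModel(**d["expression"]) if "expression" in d else ExpressionModel(),
        volume_ml=d.get("volume_ml", 3.0),
        event_clamp=tuple(d.get("event_clamp", (200, 50_000))),
        master_seed=d.get("master_seed", 1),
        composition_jitter=d.get("composition_jitter", 200.0),
    )


def save_config(config: CohortConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> CohortConfig:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))
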