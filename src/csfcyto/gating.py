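"""Declarative hierarchical gating of event matrices.

Populations are defined as conjunctions of per-channel threshold predicates
arranged in a rooted tree (root = CD45+ leukocytes).  Three node kinds are
supported:

* ``gate`` — conjunction of marker predicates, intersected with the parent;
* ``union`` — disjoint union of sibling gates (e.g. memory = CM u EM u TEMRA,
  lymphocytes = T u B u NK);
* ``remainder`` — parent events not captured by the listed siblings
  (e.g. lineage-negative ``unassigned`` cells, non-ASC B cells).

Gating is hard (binary); an event exactly at a threshold counts as positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.mixture import GaussianMixture

from .panel import HIGH_CAPABLE_CHANNELS, MarkerPanel

logger = logging.getLogger(__name__)

_STATES = ("pos", "neg", "hi", "lo")


@dataclass(frozen=True)
class MarkerPredicate:
    """One thresholded condition on one channel.

    ``pos``/``neg`` compare against the channel's primary threshold;
    ``hi`` requires a high threshold; ``lo`` means below the high threshold
    when one exists (SSC-low), otherwise below the primary (CD127-low).
    """

    channel: str
    state: str

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown predicate state {self.state!r}")
        if self.state in ("hi",) and self.channel not in HIGH_CAPABLE_CHANNELS:
            raise ValueError(f"channel {self.channel} has no high threshold")


@dataclass
class ThresholdSet:
    """Per-channel primary (pos/neg) and optional high boundary."""

    primary: dict[str, float]
    high: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, h in self.high.items():
            if ch in self.primary and h <= self.primary[ch]:
                raise ValueError(f"high threshold must exceed primary for {ch}")


def default_thresholds(panel: MarkerPanel | None = None) -> ThresholdSet:
    """Fixed thresholds matched to the default expression model."""
    panel = panel or MarkerPanel()
    primary = {ch: 2.0 for ch in panel.fluorescence}
    primary["SSC"] = 1.0
    high = {"CD27": 5.0, "CD38": 5.0, "SSC": 3.0}
    return ThresholdSet(primary=primary, high=high)


@dataclass
class PopulationDef:
    name: str
    parent: str | None
    predicates: tuple[MarkerPredicate, ...] = ()
    union_of: tuple[str, ...] = ()
    remainder_of: tuple[str, ...] = ()

    @property
    def kind(self) -> str:
        if self.union_of:
            return "union"
        if self.remainder_of:
            return "remainder"
        return "gate"


class GateTree:
    """Ordered rooted tree of population definitions."""

    def __init__(self, populations: list[PopulationDef]):
        self.populations = list(populations)
        self._by_name = {p.name: p for p in self.populations}
        self.validate()

    def __iter__(self):
        return iter(self.populations)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def node(self, name: str) -> PopulationDef:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.populations]

    def validate(self) -> None:
        seen: set[str] = set()
        roots = [p for p in self.populations if p.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        root = roots[0]
        if root.name != "leukocytes":
            raise ValueError("root population must be named 'leukocytes'")
        if not any(pr.channel == "CD45" and pr.state == "pos" for pr in root.predicates):
            raise ValueError("root must gate on CD45 positivity")
        if len(self._by_name) != len(self.populations):
            raise ValueError("population names must be unique")
        for p in self.populations:
            if p.parent is not None and p.parent not in seen:
                raise ValueError(f"parent {p.parent!r} of {p.name!r} must precede it")
            for member in p.union_of + p.remainder_of:
                if member not in seen:
                    raise ValueError(f"member {member!r} of {p.name!r} must precede it")
            if p.union_of and p.remainder_of:
                raise ValueError(f"{p.name}: union and remainder are exclusive")
            seen.add(p.name)

    def ancestors(self, name: str) -> list[str]:
        out = []
        node = self.node(name)
        while node.parent is not None:
            out.append(node.parent)
            node = self.node(node.parent)
        return out

    def channels_used(self) -> set[str]:
        return {pr.channel for p in self.populations for pr in p.predicates}

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = [{"name": p.name, "parent": p.parent,
                "predicates": [[pr.channel, pr.state] for pr in p.predicates],
                "union_of": list(p.union_of),
                "remainder_of": list(p.remainder_of)}
               for p in self.populations]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GateTree":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        pops = [PopulationDef(
            name=d["name"], parent=d["parent"],
            predicates=tuple(MarkerPredicate(c, s) for c, s in d.get("predicates", [])),
            union_of=tuple(d.get("union_of", [])),
            remainder_of=tuple(d.get("remainder_of", []))) for d in doc]
        return cls(pops)


def _g(name, parent, *preds):
    return PopulationDef(name, parent,
                         predicates=tuple(MarkerPredicate(c, s) for c, s in preds))


def default_gate_tree() -> GateTree:
    """The full CSF immunophenotyping hierarchy.

    leukocytes (CD45+) -> PMN (SSC-hi), CD14 myeloid (CD14+), non-myeloid
    (CD14- SSC-lo) -> T / B / NK / DC / unassigned; T -> CD4/CD8/DN/DP (+NKT
    overlay); CD4 and CD8 -> CD27xCD45RA quadrants with memory unions; memory
    CD4 -> CXCR3xCCR6 quadrants and activation; B -> ASC (CD27hi CD38hi) and
    non-ASC B; lymphocytes = T u B u NK.
    """
    pops = [
        _g("leukocytes", None, ("CD45", "pos")),
        _g("PMN", "leukocytes", ("SSC", "hi")),
        _g("CD14myeloid", "leukocytes", ("CD14", "pos")),
        _g("nonMyeloid", "leukocytes", ("CD14", "neg"), ("SSC", "lo")),
        _g("T", "nonMyeloid", ("CD3", "pos"), ("CD19", "neg")),
        _g("B", "nonMyeloid", ("CD3", "neg"), ("CD19", "pos")),
        _g("NK", "nonMyeloid", ("CD3", "neg"), ("CD19", "neg"), ("CD56", "pos")),
        _g("DC", "nonMyeloid", ("CD3", "neg"), ("CD19", "neg"), ("CD56", "neg"),
           ("HLA-DR", "pos"), ("CD11c", "pos")),
        PopulationDef("unassigned", "nonMyeloid", remainder_of=("T", "B", "NK", "DC")),
        PopulationDef("lymphocytes", "nonMyeloid", union_of=("T", "B", "NK")),
        # T subsets
        _g("CD4", "T", ("CD4", "pos"), ("CD8", "neg")),
        _g("CD8", "T", ("CD8", "pos"), ("CD4", "neg")),
        _g("DN", "T", ("CD4", "neg"), ("CD8", "neg")),
        _g("DP", "T", ("CD4", "pos"), ("CD8", "pos")),
        _g("NKT", "T", ("CD56", "pos")),
        # CD4 differentiation quadrants
        _g("CD4_naive", "CD4", ("CD27", "pos"), ("CD45RA", "pos")),
        _g("CD4_CM", "CD4", ("CD27", "pos"), ("CD45RA", "neg")),
        _g("CD4_EM", "CD4", ("CD27", "neg"), ("CD45RA", "neg")),
        _g("CD4_TEMRA", "CD4", ("CD27", "neg"), ("CD45RA", "pos")),
        PopulationDef("CD4_memory", "CD4", union_of=("CD4_CM", "CD4_EM", "CD4_TEMRA")),
        _g("CD4_Th1", "CD4_memory", ("CXCR3", "pos"), ("CCR6", "neg")),
        _g("CD4_Th17", "CD4_memory", ("CCR6", "pos"), ("CXCR3", "neg")),
        _g("CD4_Th1_17", "CD4_memory", ("CXCR3", "pos"), ("CCR6", "pos")),
        _g("CD4_Th_DN", "CD4_memory", ("CXCR3", "neg"), ("CCR6", "neg")),
        _g("CD4_activated", "CD4_memory", ("CD38", "pos"), ("HLA-DR", "pos")),
        _g("Treg", "CD4", ("CD25", "pos"), ("CD127", "lo")),
        # CD8 differentiation quadrants
        _g("CD8_naive", "CD8", ("CD27", "pos"), ("CD45RA", "pos")),
        _g("CD8_CM", "CD8", ("CD27", "pos"), ("CD45RA", "neg")),
        _g("CD8_EM", "CD8", ("CD27", "neg"), ("CD45RA", "neg")),
        _g("CD8_TEMRA", "CD8", ("CD27", "neg"), ("CD45RA", "pos")),
        PopulationDef("CD8_memory", "CD8", union_of=("CD8_CM", "CD8_EM", "CD8_TEMRA")),
        _g("CD8_activated", "CD8_memory", ("CD38", "pos"), ("HLA-DR", "pos")),
        # B subsets
        _g("ASC", "B", ("CD27", "hi"), ("CD38", "hi")),
        PopulationDef("B_nonASC", "B", remainder_of=("ASC",)),
    ]
    return GateTree(pops)


#: Sibling sets that partition their parent exactly, by quadrant construction.
EXHAUSTIVE_PARTITIONS: dict[str, tuple[str, ...]] = {
    "T": ("CD4", "CD8", "DN", "DP"),
    "CD4": ("CD4_naive", "CD4_CM", "CD4_EM", "CD4_TEMRA"),
    "CD8": ("CD8_naive", "CD8_CM", "CD8_EM", "CD8_TEMRA"),
    "CD4_memory": ("CD4_Th1", "CD4_Th17", "CD4_Th1_17", "CD4_Th_DN"),
    "B": ("ASC", "B_nonASC"),
    "nonMyeloid": ("T", "B", "NK", "DC", "unassigned"),
}


# ---------------------------------------------------------------------------
# Threshold estimation


def estimate_thresholds(events: pd.DataFrame, method: str = "fixed",
                        fixed_values: ThresholdSet | None = None,
                        panel: MarkerPanel | None = None,
                        max_fit_events: int = 5000,
                        min_separation: float = 3.0,
                        min_weight: float = 0.002) -> ThresholdSet:
    """Estimate per-channel gating thresholds.

    ``fixed`` returns ``fixed_values`` (default thresholds if omitted)
    unchanged.  ``midpoint-mixture`` fits, per channel, a two-component
    Gaussian location mixture and takes the midpoint of the component means
    as the primary threshold; CD27/CD38 high thresholds sit at a fixed +3.0
    offset, while on SSC the fitted midpoint *is* the low/high boundary.
    A fit whose component locations sit closer than ``min_separation``
    (default 3.0 — well under the 4-unit spacing of genuine expression
    states) or whose minor component is vanishingly small is treated as
    degenerate/unimodal and falls back to the default fixed threshold with a
    logged warning.
    """
    panel = panel or MarkerPanel()
    defaults = fixed_values if fixed_values is not None else default_thresholds(panel)
    if method == "fixed":
        return defaults
    if method != "midpoint-mixture":
        raise ValueError(f"unknown threshold method {method!r}")
    if len(events) == 0:
        raise ValueError("midpoint-mixture requires a non-empty event matrix")

    primary = dict(defaults.primary)
    high = dict(defaults.high)
    for ch in panel.channels:
        x = np.asarray(events[ch], dtype=float)
        if x.shape[0] > max_fit_events:
            # deterministic thinning keeps the fit cheap and reproducible
            idx = np.linspace(0, x.shape[0] - 1, max_fit_events).astype(int)
            x = x[idx]
        midpoint = _mixture_midpoint(x, min_separation, min_weight)
        if midpoint is None:
            logger.warning("channel %s: degenerate mixture fit; "
                           "using default threshold", ch)
            continue
        if ch == "SSC":
            high["SSC"] = midpoint
        else:
            primary[ch] = midpoint
            if ch in ("CD27", "CD38"):
                high[ch] = midpoint + 3.0
    return ThresholdSet(primary=primary, high=high)


def _mixture_midpoint(x: np.ndarray, min_separation: float,
                      min_weight: float) -> float | None:
    if np.ptp(x) < 1e-12:
        return None
    gmm = GaussianMixture(n_components=2, random_state=0, n_init=1,
                          covariance_type="spherical")
    gmm.fit(x.reshape(-1, 1))
    means = np.sort(gmm.means_.ravel())
    if (means[1] - means[0]) < min_separation or gmm.weights_.min() < min_weight:
        return None
    return float(means.mean())


# ---------------------------------------------------------------------------
# Gate application


@dataclass
class PopulationCounts:
    donor_id: str
    counts: dict[str, int]
    total_events: int

    def __getitem__(self, name: str) -> int:
        return self.counts[name]


def _predicate_mask(events: pd.DataFrame, pred: MarkerPredicate,
                    thresholds: ThresholdSet) -> np.ndarray:
    if pred.channel not in events.columns:
        raise ValueError(f"event matrix is missing channel {pred.channel!r}")
    x = events[pred.channel].to_numpy(dtype=float)
    primary = thresholds.primary.get(pred.channel)
    high = thresholds.high.get(pred.channel)
    if pred.state == "pos":
        return x >= primary
    if pred.state == "neg":
        return x < primary
    if pred.state == "hi":
        if high is None:
            raise ValueError(f"no high threshold defined for {pred.channel}")
        return x >= high
    # lo: below the high boundary when one exists, else below primary
    bound = high if high is not None else primary
    return x < bound


def gate_masks(events: pd.DataFrame, tree: GateTree,
               thresholds: ThresholdSet) -> dict[str, np.ndarray]:
    """Boolean event-membership mask for every population in the tree."""
    missing = sorted(ch for ch in tree.channels_used() if ch not in events.columns)
    if missing:
        raise ValueError(f"event matrix is missing channel(s): {', '.join(missing)}")
    n = len(events)
    masks: dict[str, np.ndarray] = {}
    for pop in tree:
        parent = masks[pop.parent] if pop.parent is not None else np.ones(n, dtype=bool)
        if pop.kind == "union":
            mask = np.zeros(n, dtype=bool)
            for member in pop.union_of:
                mask |= masks[member]
            mask &= parent
        elif pop.kind == "remainder":
            mask = parent.copy()
            for member in pop.remainder_of:
                mask &= ~masks[member]
        else:
            mask = parent.copy()
            for pred in pop.predicates:
                mask &= _predicate_mask(events, pred, thresholds)
        masks[pop.name] = mask
    return masks


def apply_gate_tree(events: pd.DataFrame, tree: GateTree,
                    thresholds: ThresholdSet,
                    donor_id: str = "") -> PopulationCounts:
    """Count events in every population of the tree."""
    masks = gate_masks(events, tree, thresholds)
    counts = {name: int(mask.sum()) for name, mask in masks.items()}
    return PopulationCounts(donor_id=donor_id, counts=counts,
                            total_events=len(events))


def counts_frame(counts_list: list[PopulationCounts]) -> pd.DataFrame:
    """Long-format (donor_id, population, count) table."""
    rows = [{"donor_id": c.donor_id, "population": name, "count": n}
            for c in counts_list for name, n in c.counts.items()]
    return pd.DataFrame(rows, columns=["donor_id", "population", "count"])
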