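"""Seeded synthetic CSF cytometry cohort generator.

Each donor gets an age (uniform over the group's age range), a CSF cell
concentration (lognormal around the group median), and an event matrix whose
rows are leukocytes sampled hierarchically: lineage from the (optionally
Dirichlet-jittered) group composition, then conditional subset draws
(CD4/CD8/DN/DP, naive vs memory with an age-dependent naive-CD8 fraction,
CM/EM/TEMRA, Th chemokine-receptor quadrants, activation, Treg, NKT and ASC
overlays).  Channel intensities are drawn from the three-state expression
model dictated by each event's latent population, and the latent label is
stored alongside the intensities so gating can be validated against ground
truth.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

from .cohort import CohortConfig, DonorRecord, GroupSpec, LINEAGES

LATENT_COLUMN = "latent_label"

_ADS_GROUPS = ("otherADS", "MOGAD", "MS")


def naive_cd8_fraction(age: float, params: tuple[float, float, float, float]) -> float:
    """Naive fraction of CD8+ T cells as a clamped decreasing line in age.

    ``clamp(intercept - slope * age, lo, hi)``: young children carry mostly
    naive CD8+ T cells in CSF, with a gradual shift toward memory phenotypes
    across the pediatric age span.
    """
    intercept, slope, lo, hi = params
    if age < 0:
        raise ValueError("age must be non-negative")
    if lo > hi:
        raise ValueError("clamp bounds out of order")
    return float(min(max(intercept - slope * age, lo), hi))


def latent_lineage(label: str) -> str:
    """Major lineage of a latent label (prefix before subset/overlay parts)."""
    return label.split("/")[0].split("+")[0]


@lru_cache(maxsize=64)
def _median_centered_alpha(comp: tuple[float, ...], total: float) -> np.ndarray:
    """Dirichlet parameters whose marginal *medians* equal ``comp``.

    A Dirichlet with parameters ``comp * total`` has marginal means equal to
    ``comp`` but, for small components, medians well below them (the Beta
    marginals are right-skewed).  Since the group composition anchors are
    cohort medians, the parameters are calibrated so each marginal Beta
    median matches its component; ``total`` still sets the jitter magnitude.
    """
    p = np.asarray(comp, dtype=float)
    alpha = p * total
    nz = alpha > 0
    for _ in range(3):
        a_total = alpha[nz].sum()
        for i in np.nonzero(nz)[0]:
            alpha[i] = brentq(
                lambda a: beta_dist.ppf(0.5, a, a_total - a) - p[i],
                1e-9, a_total - 1e-9, xtol=1e-10)
    alpha.setflags(write=False)
    return alpha


def _choice(rng: np.random.Generator, keys: list[str], probs: list[float],
            size: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    return rng.choice(len(keys), size=size, p=p)


def simulate_donor(config: CohortConfig, group: str,
                   donor_seed: int, donor_id: str | None = None
                   ) -> tuple[DonorRecord, pd.DataFrame]:
    """Simulate one donor: metadata record plus events x channels matrix.

    Identical ``(config, group, donor_seed)`` yields bit-identical output.
    """
    spec = config.group(group)
    rng = np.random.default_rng(donor_seed)
    if donor_id is None:
        donor_id = f"{group}-s{donor_seed}"

    age = float(rng.uniform(*spec.age_range))
    sex = "M" if rng.random() < 0.5 else "F"
    # draw order is identical for every group; the flag only applies to ADS
    treated = bool(rng.random() < 0.5) and group in _ADS_GROUPS
    conc = float(spec.conc_median * np.exp(spec.conc_log_sd * rng.standard_normal()))

    lo, hi = config.event_clamp
    n_events = int(np.clip(round(conc * config.volume_ml * 1000.0), lo, hi))

    # donor-level compositional jitter, median-centered on the group
    # composition so that cohort medians recover the configured anchors
    comp = np.array([spec.composition[lin] for lin in LINEAGES], dtype=float)
    if config.composition_jitter is not None:
        alpha = _median_centered_alpha(tuple(comp), config.composition_jitter)
        nz = alpha > 0
        draw = np.zeros_like(comp)
        draw[nz] = rng.dirichlet(alpha[nz])
        comp = draw

    # zero-inflated ASC presence (MOGAD / other ADS style)
    asc_fraction = spec.asc_fraction
    if spec.asc_zero_inflation > 0 and rng.random() < spec.asc_zero_inflation:
        asc_fraction = 0.0

    naive_cd8 = naive_cd8_fraction(age, spec.naive_cd8_model)

    record = DonorRecord(donor_id=donor_id, group=group, age=age, sex=sex,
                         concentration=conc, treated=treated,
                         volume_ml=config.volume_ml)
    events = _simulate_events(rng, config, spec, n_events, comp,
                              asc_fraction, naive_cd8)
    return record, events


def _simulate_events(rng: np.random.Generator, config: CohortConfig,
                     spec: GroupSpec, n: int, comp: np.ndarray,
                     asc_fraction: float, naive_cd8: float) -> pd.DataFrame:
    lineage = _choice(rng, list(LINEAGES), list(comp), n)
    lin = {name: lineage == i for i, name in enumerate(LINEAGES)}
    is_t, is_b = lin["T"], lin["B"]

    subset_keys = ["CD4", "CD8", "DN", "DP"]
    subset = _choice(rng, subset_keys, [spec.t_subsets[k] for k in subset_keys], n)
    is_cd4 = is_t & (subset == 0)
    is_cd8 = is_t & (subset == 1)
    is_dp = is_t & (subset == 3)

    # naive vs memory: CD4 memory fraction fixed; CD8 (and DN/DP) follow the
    # donor's age-dependent naive fraction
    u_mem = rng.random(n)
    memory = np.where(is_cd4, u_mem < spec.cd4_memory_fraction,
                      u_mem < 1.0 - naive_cd8) & is_t

    mem_keys = ["CM", "EM", "TEMRA"]
    mem_cd4 = _choice(rng, mem_keys, [spec.cd4_memory_states[k] for k in mem_keys], n)
    mem_cd8 = _choice(rng, mem_keys, [spec.cd8_memory_states[k] for k in mem_keys], n)
    mem_state = np.where(is_cd4, mem_cd4, mem_cd8)

    th_keys = ["Th1", "Th17", "Th1_17", "Th_DN"]
    th_state = _choice(rng, th_keys, [spec.th_states[k] for k in th_keys], n)

    u_act = rng.random(n)
    activated = memory & np.where(is_cd4, u_act < spec.cd4_activated_fraction,
                                  np.where(is_cd8, u_act < spec.cd8_activated_fraction,
                                           False))
    treg = is_cd4 & (rng.random(n) < spec.treg_fraction)
    nkt = is_t & (rng.random(n) < spec.nkt_fraction)
    asc = is_b & (rng.random(n) < asc_fraction)

    naive = is_t & ~memory
    cm = memory & (mem_state == 0)
    temra = memory & (mem_state == 2)
    cd4mem = is_cd4 & memory

    # channel state codes: 0 = neg/lo, 1 = pos, 2 = hi
    codes = {ch: np.zeros(n, dtype=np.int8) for ch in config.panel.channels}
    codes["CD45"][:] = 1
    codes["CD14"][lin["CD14myeloid"]] = 1
    codes["CD3"][is_t] = 1
    codes["CD19"][is_b] = 1
    codes["CD56"][lin["NK"] | nkt] = 1
    codes["HLA-DR"][lin["CD14myeloid"] | lin["DC"] | is_b | activated] = 1
    codes["CD4"][is_cd4 | is_dp] = 1
    codes["CD8"][is_cd8 | is_dp] = 1
    codes["CD38"][activated] = 1
    codes["CD38"][asc] = 2
    codes["CD27"][(is_b & ~asc) | naive | cm] = 1
    codes["CD27"][asc] = 2
    codes["CD45RA"][naive | temra] = 1
    codes["CD11c"][lin["CD14myeloid"] | lin["DC"]] = 1
    codes["CD127"][is_t & ~treg] = 1
    codes["CD25"][treg] = 1
    codes["CXCR3"][cd4mem & ((th_state == 0) | (th_state == 2))] = 1
    codes["CCR6"][cd4mem & ((th_state == 1) | (th_state == 2))] = 1
    codes["SSC"][lin["PMN"]] = 1

    expr = config.expression
    mu_fluor = np.array([expr.mu_neg, expr.mu_pos, expr.mu_hi])
    mu_ssc = np.array([expr.ssc_mu_lo, expr.ssc_mu_hi])
    data = {}
    for ch in config.panel.channels:
        if ch == "SSC":
            mu, sigma = mu_ssc[codes[ch]], expr.ssc_sigma
        else:
            mu, sigma = mu_fluor[codes[ch]], expr.sigma
        data[ch] = mu + sigma * rng.standard_normal(n)

    data[LATENT_COLUMN] = _labels(lineage, subset, memory, mem_state, th_state,
                                  activated, treg, nkt, asc)
    return pd.DataFrame(data, columns=list(config.panel.channels) + [LATENT_COLUMN])


def _labels(lineage, subset, memory, mem_state, th_state,
            activated, treg, nkt, asc) -> list[str]:
    subset_keys = ("CD4", "CD8", "DN", "DP")
    mem_keys = ("CM", "EM", "TEMRA")
    th_keys = ("Th1", "Th17", "Th1_17", "Th_DN")
    labels = []
    for i in range(lineage.shape[0]):
        lin = LINEAGES[lineage[i]]
        if lin == "T":
            parts = ["T", subset_keys[subset[i]]]
            if memory[i]:
                parts.append("mem")
                parts.append(mem_keys[mem_state[i]])
                if subset_keys[subset[i]] == "CD4":
                    parts.append(th_keys[th_state[i]])
            else:
                parts.append("naive")
            label = "/".join(parts)
            if activated[i]:
                label += "+act"
            if treg[i]:
                label += "+treg"
            if nkt[i]:
                label += "+nkt"
        elif lin == "B":
            label = "B/ASC" if asc[i] else "B/nonASC"
        else:
            label = lin
        labels.append(label)
    return labels


def simulate_cohort(config: CohortConfig
                    ) -> tuple[list[DonorRecord], list[pd.DataFrame]]:
    """Simulate every configured group; donor seed_i = master_seed + i."""
    records: list[DonorRecord] = []
    matrices: list[pd.DataFrame] = []
    i = 0
    for spec in config.groups:
        for j in range(spec.n_donors):
            donor_id = f"{spec.label}-{j + 1:02d}"
            rec, events = simulate_donor(config, spec.label,
                                         config.master_seed + i, donor_id)
            records.append(rec)
            matrices.append(events)
            i += 1
    return records, matrices


def metadata_frame(records: list[DonorRecord]) -> pd.DataFrame:
    """Cohort-level metadata table (one row per donor)."""
    return pd.DataFrame([{
        "donor_id": r.donor_id, "group": r.group, "age": r.age, "sex": r.sex,
        "concentration_cells_per_uL": r.concentration, "treated": r.treated,
        "volume_mL": r.volume_ml,
    } for r in records])
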