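"""Synthetic fixtures: eplet registries, haplotype-frequency tables, and
full cohorts with the statistical structure the analysis assumes.

The cohort generator draws donor/recipient haplotypes from an
ethnicity-matched frequency table and produces per-locus latent dnDSA
times that are exponential with hazard
``lambda0 * exp(beta * max single-molecule mismatch) * cni_multiplier``.
Latent events are interval-detected at annual screens (a switch emits
exact-time detections for clean oracle tests), with MFI drawn from a
two-component distribution so the >=500 filter is non-trivial.
All output is deterministic under (seed, params).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import DAYS_PER_YEAR, CohortRecord, Detection
from .errors import ContractError, ValidationError
from .registry import (
    AlleleCall,
    EpletRegistry,
    Haplotype,
    HaplotypeFrequencyTable,
    SubjectTyping,
    allele_locus,
    first_field,
)

DEFAULT_POPULATIONS = ["Chinese", "Malay", "Indian", "Other"]

_NORM_Q75 = 0.6744897501960817  # standard normal 75th percentile


# ---------------------------------------------------------------------------
# Registry / frequency-table fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticRegistrySpec:
    """Shape of the generated registry.

    The defaults guarantee structural extremes: one DRB1 allele carrying 21
    private eplets and one DQ heterodimer carrying 32 (12 alpha + 20 beta),
    so realized pairwise molecule mismatches can span 0-21 (DR) and
    0-32 (DQ).
    """

    n_drb1: int = 10
    n_dr_eplets: int = 40
    n_dqa1: int = 8
    n_dqa_eplets: int = 15
    n_dqb1: int = 8
    n_dqb_eplets: int = 25

    def __post_init__(self):
        if min(self.n_dr_eplets, self.n_dqa_eplets, self.n_dqb_eplets) <= 0:
            raise ValidationError("registry spec would force empty eplet sets")
        if self.n_drb1 < 2 or self.n_dqa1 < 2 or self.n_dqb1 < 2:
            raise ValidationError("need at least two alleles per locus")
        if self.n_dr_eplets < 22 or self.n_dqa_eplets < 13 or self.n_dqb_eplets < 21:
            raise ValidationError(
                "eplet pools too small for the guaranteed mismatch extremes"
            )


_DRB1_GROUPS = ["03", "04", "07", "08", "09", "10", "11", "12", "13", "14", "16"]
_DQA1_GROUPS = ["02", "03", "04", "06"]
_DQB1_GROUPS = ["02", "04", "06"]


def generate_fixture_registry(
    spec: SyntheticRegistrySpec | None = None, seed: int = 0
) -> EpletRegistry:
    """Deterministically generate a registry matching ``spec``."""
    spec = spec or SyntheticRegistrySpec()
    rng = np.random.default_rng(seed)
    dr_pool = [f"dr{i:03d}" for i in range(1, spec.n_dr_eplets + 1)]
    dr_high = dr_pool[:21]  # private block for DRB1*15:01
    dr_low = dr_pool[21:]
    dqa_pool = [f"dqa{i:03d}" for i in range(1, spec.n_dqa_eplets + 1)]
    dqb_pool = [f"dqb{i:03d}" for i in range(1, spec.n_dqb_eplets + 1)]

    mapping: dict[str, set[str]] = {}
    mapping["DRB1*15:01"] = set(dr_high)
    mapping["DRB1*01:01"] = set(rng.choice(dr_low, size=4, replace=False))
    for g in _DRB1_GROUPS[: spec.n_drb1 - 2]:
        size = int(rng.integers(3, 16))
        mapping[f"DRB1*{g}:01"] = set(rng.choice(dr_pool, size=size, replace=False))
    for allele in (
        "DRB3*01:01", "DRB3*02:02",
        "DRB4*01:01", "DRB4*01:03",
        "DRB5*01:01", "DRB5*02:02",
    ):
        size = int(rng.integers(2, 9))
        mapping[allele] = set(rng.choice(dr_pool, size=size, replace=False))

    mapping["DQA1*05:01"] = set(dqa_pool[:12])
    mapping["DQA1*01:01"] = set(rng.choice(dqa_pool[12:], size=2, replace=False))
    for g in _DQA1_GROUPS[: spec.n_dqa1 - 2]:
        size = int(rng.integers(2, 11))
        mapping[f"DQA1*{g}:01"] = set(rng.choice(dqa_pool, size=size, replace=False))

    mapping["DQB1*03:01"] = set(dqb_pool[:20])
    mapping["DQB1*05:01"] = set(rng.choice(dqb_pool[20:], size=3, replace=False))
    for g in _DQB1_GROUPS[: spec.n_dqb1 - 2]:
        size = int(rng.integers(2, 15))
        mapping[f"DQB1*{g}:01"] = set(rng.choice(dqb_pool, size=size, replace=False))
    # extra second-field variants to exercise imputation ambiguity
    if spec.n_dqb1 >= 6:
        mapping["DQB1*05:02"] = set(rng.choice(dqb_pool, size=4, replace=False))
    if spec.n_drb1 >= 4:
        mapping["DRB1*15:02"] = set(rng.choice(dr_pool, size=6, replace=False))
    return EpletRegistry(mapping)


def generate_frequency_table(
    registry: EpletRegistry,
    populations: list[str] | None = None,
    seed: int = 0,
    n_haplotypes: int = 30,
) -> HaplotypeFrequencyTable:
    """Dirichlet-sampled, population-shifted haplotype frequencies.

    Each population's frequencies sum to 1 and each population has a
    distinct most-frequent haplotype (population ``p`` gets haplotype ``p``
    boosted above the rest).
    """
    populations = populations or DEFAULT_POPULATIONS
    rng = np.random.default_rng(seed)
    drb1s = registry.alleles("DRB1")
    drb345s = (
        registry.alleles("DRB3") + registry.alleles("DRB4") + registry.alleles("DRB5")
    )
    dqa1s = registry.alleles("DQA1")
    dqb1s = registry.alleles("DQB1")
    haps: list[Haplotype] = [
        Haplotype("DRB1*15:01", "DRB5*01:01", "DQA1*05:01", "DQB1*03:01"),
        Haplotype("DRB1*01:01", "", "DQA1*01:01", "DQB1*05:01"),
    ]
    seen = {h.key() for h in haps}
    while len(haps) < n_haplotypes:
        h = Haplotype(
            drb1=str(rng.choice(drb1s)),
            drb345="" if rng.random() < 0.3 else str(rng.choice(drb345s)),
            dqa1=str(rng.choice(dqa1s)),
            dqb1=str(rng.choice(dqb1s)),
        )
        if h.key() not in seen:
            seen.add(h.key())
            haps.append(h)
    rows = []
    n = len(haps)
    for p, pop in enumerate(populations):
        w = rng.dirichlet(np.full(n, 0.6))
        boost = p % n
        w[boost] = w.max() * 1.5  # guarantees a population-specific mode
        w = w / w.sum()
        for h, f in zip(haps, w):
            rows.append(
                {
                    "population": pop,
                    "DRB1": h.drb1,
                    "DRB345": h.drb345,
                    "DQA1": h.dqa1,
                    "DQB1": h.dqb1,
                    "frequency": float(f),
                }
            )
    return HaplotypeFrequencyTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _default_ethnicity_mix() -> dict[str, float]:
    return {"Chinese": 0.65, "Malay": 0.17, "Indian": 0.14, "Other": 0.04}


def _default_antimetabolite_mix() -> dict[str, float]:
    return {"mycophenolate": 0.88, "azathioprine": 0.11, "none": 0.01}


@dataclass
class SimulationParams:
    n_pairs: int
    seed: int
    ethnicity_mix: dict[str, float] = field(default_factory=_default_ethnicity_mix)
    deceased_donor_frac: float = 0.44
    cyclosporine_frac: float = 0.71
    antimetabolite_mix: dict[str, float] = field(
        default_factory=_default_antimetabolite_mix
    )
    thymoglobulin_frac: float = 0.19
    beta_dr: float = math.log(1.3)  # per-eplet log-hazard, DR
    beta_dq: float = math.log(1.1)  # per-eplet log-hazard, DQ
    cni_hr: float = 1.66  # cyclosporine-vs-tacrolimus hazard multiplier
    lambda0_dr: float = 0.004
    lambda0_dq: float = 0.015
    followup_median: float = 5.4
    followup_iqr: tuple[float, float] = (3.3, 8.0)
    screening_interval_years: float = 1.0
    detection_prob: float = 0.9
    mfi_cutoff: float = 500.0
    exact_times: bool = False
    low_res_fraction: float = 0.10

    def __post_init__(self):
        if self.n_pairs <= 0:
            raise ContractError("n_pairs must be positive")
        if self.seed is None:
            raise ContractError("seed is mandatory")
        for name, mix in (
            ("ethnicity_mix", self.ethnicity_mix),
            ("antimetabolite_mix", self.antimetabolite_mix),
        ):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1")
        if min(self.lambda0_dr, self.lambda0_dq) <= 0:
            raise ValidationError("baseline hazards must be positive")
        if not 0 <= self.low_res_fraction <= 1:
            raise ValidationError("low_res_fraction must be in [0, 1]")


class _HaplotypeUniverse:
    """Indexed haplotypes with per-population sampling weights and
    precomputed molecule eplet sets for fast mismatch maxima."""

    def __init__(self, registry: EpletRegistry, freq: HaplotypeFrequencyTable):
        self.haps: list[Haplotype] = []
        index: dict[str, int] = {}
        self.pop_probs: dict[str, np.ndarray] = {}
        pop_weights: dict[str, dict[int, float]] = {}
        for pop in freq.populations:
            weights = {}
            for h, f in freq.haplotypes(pop):
                if h.key() not in index:
                    index[h.key()] = len(self.haps)
                    self.haps.append(h)
                weights[index[h.key()]] = weights.get(index[h.key()], 0.0) + f
            pop_weights[pop] = weights
        n = len(self.haps)
        for pop, weights in pop_weights.items():
            v = np.zeros(n)
            for i, f in weights.items():
                v[i] = f
            total = v.sum()
            if total <= 0:
                raise ValidationError(f"population {pop} has zero total frequency")
            self.pop_probs[pop] = v / total
        # per-haplotype molecule eplet sets
        self.dr_mols: list[list[tuple[str, frozenset[str]]]] = []
        self.dq_set: list[frozenset[str]] = []
        self.dq_beta: list[str] = []
        for h in self.haps:
            mols = [(h.drb1, registry.eplet_set(h.drb1))]
            if h.drb345:
                mols.append((h.drb345, registry.eplet_set(h.drb345)))
            self.dr_mols.append(mols)
            self.dq_set.append(registry.eplet_set(h.dqa1) | registry.eplet_set(h.dqb1))
            self.dq_beta.append(h.dqb1)
        self._cache: dict[tuple[int, int, int, int], tuple[int, int, str, str]] = {}

    def maxima(self, d1: int, d2: int, r1: int, r2: int):
        """(dr_max, dq_max, dr_specificity_allele, dq_specificity_allele)."""
        if d1 > d2:
            d1, d2 = d2, d1
        if r1 > r2:
            r1, r2 = r2, r1
        key = (d1, d2, r1, r2)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        r_dr_union = frozenset().union(
            *(s for _, s in self.dr_mols[r1]), *(s for _, s in self.dr_mols[r2])
        )
        r_dq_union = self.dq_set[r1] | self.dq_set[r2]
        dr_max, dr_allele = 0, self.dr_mols[d1][0][0]
        for h in (d1, d2):
            for allele, s in self.dr_mols[h]:
                c = len(s - r_dr_union)
                if c > dr_max:
                    dr_max, dr_allele = c, allele
        dq_max, dq_allele = 0, self.dq_beta[d1]
        for h in (d1, d2):
            c = len(self.dq_set[h] - r_dq_union)
            if c > dq_max:
                dq_max, dq_allele = c, self.dq_beta[h]
        out = (dr_max, dq_max, dr_allele, dq_allele)
        self._cache[key] = out
        return out


def _typing_from_haps(
    subject_id: str,
    role: str,
    pair_id: str,
    ethnicity: str,
    h1: Haplotype,
    h2: Haplotype,
    degrade: bool = False,
) -> SubjectTyping:
    def drb345_call(allele: str) -> AlleleCall:
        if allele == "":
            return AlleleCall("DRB345", "", "null")
        if degrade:
            return AlleleCall(allele_locus(allele), first_field(allele), "low_res")
        return AlleleCall(allele_locus(allele), allele, "two_field")

    def call(locus: str, allele: str) -> AlleleCall:
        if degrade and locus == "DQA1":
            return AlleleCall(locus, "", "absent")
        if degrade:
            return AlleleCall(locus, first_field(allele), "low_res")
        return AlleleCall(locus, allele, "two_field")

    return SubjectTyping(
        subject_id=subject_id,
        role=role,
        pair_id=pair_id,
        ethnicity=ethnicity,
        slots={
            "DRB1": [call("DRB1", h1.drb1), call("DRB1", h2.drb1)],
            "DRB345": [drb345_call(h1.drb345), drb345_call(h2.drb345)],
            "DQA1": [call("DQA1", h1.dqa1), call("DQA1", h2.dqa1)],
            "DQB1": [call("DQB1", h1.dqb1), call("DQB1", h2.dqb1)],
        },
    )


def simulate_cohort(
    params: SimulationParams,
    registry: EpletRegistry,
    freq_table: HaplotypeFrequencyTable,
):
    """Simulate a donor-recipient cohort.

    Returns ``(typings, records, truth)``:

    * ``typings`` - list of :class:`SubjectTyping` (donor + recipient per
      pair; a ``low_res_fraction`` of subjects is degraded to exercise the
      imputation path, but the ground truth is always computed from the
      true haplotypes);
    * ``records`` - list of :class:`~epletmm.cohort.CohortRecord` with
      detections emitted per the screening model;
    * ``truth`` - DataFrame with generating maxima, latent and observed
      event times, and covariates.
    """
    rng = np.random.default_rng(params.seed)
    uni = _HaplotypeUniverse(registry, freq_table)
    pops = list(params.ethnicity_mix)
    pop_p = np.array([params.ethnicity_mix[p] for p in pops])
    missing = [p for p in pops if p not in uni.pop_probs]
    if missing:
        raise ValidationError(f"frequency table lacks populations: {missing}")
    n = params.n_pairs
    eth_idx = rng.choice(len(pops), size=n, p=pop_p)
    sigma = (
        math.log(params.followup_iqr[1]) - math.log(params.followup_iqr[0])
    ) / (2 * _NORM_Q75)
    followups = rng.lognormal(math.log(params.followup_median), sigma, size=n)
    cyclo = rng.random(n) < params.cyclosporine_frac
    deceased = rng.random(n) < params.deceased_donor_frac
    thymo = rng.random(n) < params.thymoglobulin_frac
    am_levels = list(params.antimetabolite_mix)
    am_idx = rng.choice(
        len(am_levels), size=n, p=np.array([params.antimetabolite_mix[a] for a in am_levels])
    )
    degrade_flags = rng.random(2 * n) < params.low_res_fraction

    typings: list[SubjectTyping] = []
    records: list[CohortRecord] = []
    truth_rows = []
    for i in range(n):
        pid = f"P{i + 1:05d}"
        pop = pops[eth_idx[i]]
        probs = uni.pop_probs[pop]
        r1, r2, d1, d2 = rng.choice(len(uni.haps), size=4, p=probs)
        dr_max, dq_max, dr_spec, dq_spec = uni.maxima(d1, d2, r1, r2)
        fu = float(followups[i])
        cni = "cyclosporine" if cyclo[i] else "tacrolimus"
        mult = params.cni_hr if cyclo[i] else 1.0
        rate_dr = params.lambda0_dr * math.exp(params.beta_dr * dr_max) * mult
        rate_dq = params.lambda0_dq * math.exp(params.beta_dq * dq_max) * mult
        latent_dr = float(rng.exponential(1.0 / rate_dr))
        latent_dq = float(rng.exponential(1.0 / rate_dq))
        detections = _emit_detections(
            rng, params, (("DR", latent_dr, dr_spec), ("DQ", latent_dq, dq_spec)), fu
        )
        rec = CohortRecord(
            pair_id=pid,
            ethnicity=pop,
            donor_type="deceased" if deceased[i] else "living",
            cni=cni,
            antimetabolite=am_levels[am_idx[i]],
            induction="thymoglobulin" if thymo[i] else "basiliximab",
            follow_up_years=fu,
            detections=detections,
            flags={},
        )
        records.append(rec)
        typings.append(
            _typing_from_haps(
                f"R{i + 1:05d}", "recipient", pid, pop,
                uni.haps[r1], uni.haps[r2], degrade=bool(degrade_flags[2 * i]),
            )
        )
        typings.append(
            _typing_from_haps(
                f"D{i + 1:05d}", "donor", pid, pop,
                uni.haps[d1], uni.haps[d2], degrade=bool(degrade_flags[2 * i + 1]),
            )
        )
        truth_rows.append(
            {
                "pair_id": pid,
                "ethnicity": pop,
                "donor_type": rec.donor_type,
                "cni": cni,
                "antimetabolite": rec.antimetabolite,
                "induction": rec.induction,
                "follow_up_years": fu,
                "dr_max": dr_max,
                "dq_max": dq_max,
                "latent_dr": latent_dr,
                "latent_dq": latent_dq,
                "time_dr": min(latent_dr, fu),
                "event_dr": int(latent_dr <= fu),
                "time_dq": min(latent_dq, fu),
                "event_dq": int(latent_dq <= fu),
            }
        )
    truth = pd.DataFrame(truth_rows)
    return typings, records, truth


def _emit_detections(rng, params: SimulationParams, latents, follow_up: float):
    """Detection rows for one recipient under the screening model."""
    out: list[Detection] = []
    for _, latent, spec in latents:
        if latent > follow_up:
            continue
        if params.exact_times:
            mfi = float(500.0 + rng.lognormal(7.5, 0.7))
            out.append(Detection(day=latent * DAYS_PER_YEAR, specificity=spec, mfi=mfi))
            continue
        step = params.screening_interval_years
        screen = math.ceil(latent / step) * step
        missed_logged = False
        while screen <= follow_up + 1e-9:
            if rng.random() < params.detection_prob:
                mfi = float(500.0 + rng.lognormal(7.5, 0.7))
                out.append(
                    Detection(day=screen * DAYS_PER_YEAR, specificity=spec, mfi=mfi)
                )
                break
            if not missed_logged:
                out.append(
                    Detection(
                        day=screen * DAYS_PER_YEAR,
                        specificity=spec,
                        mfi=float(rng.uniform(50, 450)),
                    )
                )
                missed_logged = True
            screen += step
    out.sort(key=lambda d: d.day)
    return out


def simulate_molecule_level_dataset(
    n_recipients: int,
    seed: int,
    t_dr: int = 12,
    t_dq: int = 15,
    p_below: float = 0.001,
    p_above: float = 0.25,
    link: str = "step",
    logistic_intercept: float = -3.0,
    logistic_slope: float = 0.2,
    dr_score_max: int = 21,
    dq_score_max: int = 32,
):
    """Labelled molecule-level scores for cutpoint-recovery experiments.

    Returns ``(molecule_data, summaries)`` where ``molecule_data`` maps
    ``"DR"``/``"DQ"`` to frames (pair_id, score, label) and ``summaries``
    carries each recipient's per-class maxima.  ``link="step"`` jumps the
    label probability from ``p_below`` to ``p_above`` at the change-point;
    ``link="logistic"`` uses ``expit(intercept + slope * score)``.
    """
    if link not in ("step", "logistic"):
        raise ContractError(f"unknown link {link!r}")
    rng = np.random.default_rng(seed)
    frames = {"DR": [], "DQ": []}
    summary_rows = []
    for i in range(n_recipients):
        pid = f"P{i + 1:05d}"
        n_dr = int(rng.integers(2, 5))
        dr_scores = rng.integers(0, dr_score_max + 1, size=n_dr)
        dq_scores = rng.integers(0, dq_score_max + 1, size=2)
        for cls, scores, t in (("DR", dr_scores, t_dr), ("DQ", dq_scores, t_dq)):
            for s in scores:
                if link == "step":
                    p = p_above if s >= t else p_below
                else:
                    p = 1.0 / (1.0 + math.exp(-(logistic_intercept + logistic_slope * s)))
                frames[cls].append(
                    {"pair_id": pid, "score": int(s), "label": int(rng.random() < p)}
                )
        summary_rows.append(
            {
                "pair_id": pid,
                "dr_max": int(dr_scores.max()),
                "dq_max": int(dq_scores.max()),
            }
        )
    molecule_data = {
        cls: pd.DataFrame(rows, columns=["pair_id", "score", "label"])
        for cls, rows in frames.items()
    }
    return molecule_data, pd.DataFrame(summary_rows)
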