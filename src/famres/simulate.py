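"""Synthetic pedigrees and FFQ-like trait data with known familial structure.

The generator emulates a multigenerational urban cohort: founder couples
with 0-6 offspring, an optional third generation (offspring who marry
unrelated simulated spouses and have children), and a sizeable fraction of
singletons.  Latent trait values follow the additive-genetic model run
generatively (gene dropping), plus a shared-household environmental factor
and an extra spousal (couple) environmental factor, so every downstream
estimator can be checked against closed-form pair covariances.

Household model.  Each couple anchors one household factor.  Founders load
1.0 on their own household; their offspring load ``household_attenuation``
(lambda < 1) on the parental household — adult offspring are only partly
attached to the parental food environment.  Offspring who marry additionally
load sqrt(1 - lambda^2) on their new couple household.  Spouses also share a
couple-specific factor with variance ``c_spouse``.  Residual variance tops
every individual up to unit latent variance.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import FEMALE, MALE, Individual, Pedigree

#: Calendar year of the first simulated survey wave (index 3).
BASE_YEAR = 2006
#: Surveys are repeated on a fixed 3-year cycle.
SURVEY_INTERVAL_YEARS = 3
#: First survey wave index carrying dietary data.
FIRST_SURVEY = 3
#: Reference age subtracted before applying the age effect.
REFERENCE_AGE = 42.0


@dataclass(frozen=True)
class TraitSpec:
    """Observed scale of one simulated trait.

    ``mean``/``sd`` give the affine map from the latent N(0,1) value to the
    nutrient scale; ``h2``/``age_effect`` override the config-wide values
    when set.
    """

    name: str
    unit: str
    mean: float
    sd: float
    h2: float | None = None
    age_effect: float | None = None


#: Observed scales for the default traits (energy and the three macros),
#: chosen to look like an adult FFQ cohort.  Cosmetic only: no test or
#: acceptance check depends on these numbers.
DEFAULT_TRAITS = (
    TraitSpec("energy", "kcal/d", 2411.0, 838.0),
    TraitSpec("carbohydrate", "g/d", 341.0, 116.0),
    TraitSpec("protein", "g/d", 84.6, 38.3),
    TraitSpec("fat", "g/d", 78.7, 38.0),
)


@dataclass
class SimConfig:
    """Study-design and variance-structure knobs for the generator.

    Defaults target the structure of a large family cohort: ~36% of
    families are singletons, the rest are founder couples whose offspring
    distribution yields a mean family size near 3.2, a quarter to a third
    of surveyed participants have repeated measurements, and ~6% of
    person-surveys carry implausible energy values (under/over-reporting).
    """

    n_families: int = 500
    singleton_fraction: float = 0.3624
    generations: int = 3
    #: P(number of offspring = k), k = 0..6, for founder couples.
    offspring_dist: Sequence[float] = (0.26, 0.34, 0.23, 0.10, 0.04, 0.02, 0.01)
    #: probability a second-generation offspring marries (generations=3).
    marry_prob: float = 0.3
    #: P(number of offspring = k), k = 0..3, for third-generation couples.
    gen3_offspring_dist: Sequence[float] = (0.2, 0.3, 0.3, 0.2)
    h2: float = 0.2
    c_spouse: float = 0.2
    c_house: float = 0.15
    #: lambda: offspring loading on the parental household factor.
    household_attenuation: float = 0.6
    age_effect: float = 0.0
    #: P(person has 1, 2, 3, 4 survey measurements).
    n_surveys_dist: Sequence[float] = (0.335, 0.335, 0.255, 0.075)
    #: within-person survey noise, as a coefficient of variation of the mean.
    survey_cv: float = 0.15
    #: fraction of person-surveys with energy planted outside [800, 4200].
    outlier_fraction: float = 0.064
    seed: int | None = None
    traits: Sequence[TraitSpec] = DEFAULT_TRAITS

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory for reproducibility")
        for name in ("singleton_fraction", "marry_prob", "survey_cv",
                     "outlier_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} out of [0, 1]")
        for name in ("h2", "c_spouse", "c_house"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name}={v} out of [0, 1)")
        if self.h2 + self.c_spouse + self.c_house >= 1.0:
            raise ValueError("h2 + c_spouse + c_house must be < 1")
        if not 0.0 <= self.household_attenuation <= 1.0:
            raise ValueError("household_attenuation out of [0, 1]")
        if self.generations not in (2, 3):
            raise ValueError("generations must be 2 or 3")
        for name in ("offspring_dist", "gen3_offspring_dist", "n_surveys_dist"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.min() < 0 or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} is not a probability vector")
        if (
            self.generations == 3
            and self.marry_prob > 0
            and float(np.asarray(self.offspring_dist)[0]) >= 1.0
        ):
            raise ValueError(
                "generations=3 infeasible: offspring distribution degenerate at 0"
            )

    def trait_h2(self, t: TraitSpec) -> float:
        return self.h2 if t.h2 is None else t.h2

    def trait_age_effect(self, t: TraitSpec) -> float:
        return self.age_effect if t.age_effect is None else t.age_effect


@dataclass
class SimulatedPedigree:
    """A generated pedigree plus the structure needed to simulate traits.

    ``index`` lists (fid, iid) keys in a parents-before-children order;
    the parallel arrays drive vectorised gene dropping and the household
    factor model.  ``relation_counts`` is the generator's own bookkeeping
    of the relative pairs it created (used to cross-check classification).
    """

    pedigree: Pedigree
    index: list[tuple[str, str]]
    father_idx: np.ndarray  # -1 when absent
    mother_idx: np.ndarray
    level: np.ndarray  # 0 founders, 1 their offspring, 2 grandchildren
    sex: np.ndarray  # object array of "male"/"female"
    birth_year: np.ndarray
    # household factor memberships: up to two (factor, loading) per person
    house1_idx: np.ndarray
    house1_load: np.ndarray
    house2_idx: np.ndarray
    house2_load: np.ndarray
    n_households: int
    couple_idx: np.ndarray  # -1 when not part of a couple
    n_couples: int
    relation_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.index)

    def ages_at(self, year: float) -> np.ndarray:
        return year - self.birth_year


def _sample_counts(rng: np.random.Generator, dist: Sequence[float], size: int):
    return rng.choice(len(dist), size=size, p=np.asarray(dist, dtype=float))


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimulatedPedigree:
    """Generate families of founders, offspring and (optionally) grandchildren.

    Family layout: with probability ``singleton_fraction`` a family is one
    unrelated adult; otherwise a founder couple with ``offspring_dist``
    children.  When ``generations == 3`` each child marries an unrelated
    simulated spouse with probability ``marry_prob`` and has
    ``gen3_offspring_dist`` children.  All individuals are sexed; ages are
    generation-stratified so the adult-cohort mean lands near 42 years.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lam = cfg.household_attenuation
    lam_own = math.sqrt(max(0.0, 1.0 - lam * lam))

    individuals: list[Individual] = []
    index: list[tuple[str, str]] = []
    fa_i: list[int] = []
    mo_i: list[int] = []
    level: list[int] = []
    h1_idx: list[int] = []
    h1_load: list[float] = []
    h2_idx: list[int] = []
    h2_load: list[float] = []
    couple_i: list[int] = []
    counts: Counter[str] = Counter()
    n_house = 0
    n_couples = 0

    is_singleton = rng.random(cfg.n_families) < cfg.singleton_fraction
    n_offspring = _sample_counts(rng, cfg.offspring_dist, cfg.n_families)

    def add_person(fid, iid, father, mother, sex, byear, fa, mo, lev,
                   houses, couple):
        byear = min(byear, BASE_YEAR - 18.0)  # adult cohort at baseline
        individuals.append(Individual(fid, iid, father, mother, sex, int(byear)))
        index.append((fid, iid))
        fa_i.append(fa)
        mo_i.append(mo)
        level.append(lev)
        (i1, l1), (i2, l2) = (houses + [(-1, 0.0), (-1, 0.0)])[:2]
        h1_idx.append(i1)
        h1_load.append(l1)
        h2_idx.append(i2)
        h2_load.append(l2)
        couple_i.append(couple)
        return len(index) - 1

    for f in range(cfg.n_families):
        fid = f"F{f + 1}"
        if is_singleton[f]:
            sex = MALE if rng.random() < 0.5 else FEMALE
            byear = BASE_YEAR - rng.normal(45.0, 16.0)
            house = n_house
            n_house += 1
            add_person(fid, "1", None, None, sex, byear, -1, -1, 0,
                       [(house, 1.0)], -1)
            continue
        house0 = n_house
        n_house += 1
        couple0 = n_couples
        n_couples += 1
        counts["couples_total"] += 1
        # spouse pairs are recognisable from parent links only when the
        # couple has >=1 offspring in the pedigree
        if n_offspring[f] > 0:
            counts["spouse"] += 1
        # founders are older in three-generation families so that
        # grandchildren still belong to the adult cohort
        founder_age = 58.0 if cfg.generations == 2 else 72.0
        f_by = BASE_YEAR - rng.normal(founder_age, 7.0)
        m_by = f_by + rng.normal(3.0, 2.0)
        fa = add_person(fid, "1", None, None, MALE, f_by, -1, -1, 0,
                        [(house0, 1.0)], couple0)
        mo = add_person(fid, "2", None, None, FEMALE, m_by, -1, -1, 0,
                        [(house0, 1.0)], couple0)
        next_iid = 3
        children: list[tuple[int, str, str]] = []  # (idx, iid, sex)
        for _ in range(n_offspring[f]):
            sex = MALE if rng.random() < 0.5 else FEMALE
            byear = max(f_by, m_by) + rng.uniform(25.0, 33.0)
            iid = str(next_iid)
            next_iid += 1
            counts["father-son" if sex == MALE else "father-daughter"] += 1
            counts["mother-son" if sex == MALE else "mother-daughter"] += 1
            children.append(
                (add_person(fid, iid, "1", "2", sex, byear, fa, mo, 1,
                            [(house0, lam)], -1), iid, sex)
            )
        for (_, _, sa), (_, _, sb) in _unordered_pairs(children):
            if sa == sb:
                counts["sister-sister" if sa == FEMALE else "brother-brother"] += 1
            else:
                counts["brother-sister"] += 1
        if cfg.generations == 3:
            married: list[tuple[int, str, int]] = []  # (child idx, iid, n gc)
            gc_of: dict[str, int] = {}
            for child_idx, child_iid, child_sex in children:
                if rng.random() >= cfg.marry_prob:
                    continue
                house1 = n_house
                n_house += 1
                couple1 = n_couples
                n_couples += 1
                counts["couples_total"] += 1
                # re-register the child with a loading on the new household
                h2_idx[child_idx] = house1
                h2_load[child_idx] = lam_own
                couple_i[child_idx] = couple1
                sp_sex = FEMALE if child_sex == MALE else MALE
                sp_by = individuals[child_idx].birth_year + rng.normal(0.0, 3.0)
                sp_iid = str(next_iid)
                next_iid += 1
                sp = add_person(fid, sp_iid, None, None, sp_sex, sp_by,
                                -1, -1, 1, [(house1, 1.0)], couple1)
                n_gc = int(_sample_counts(rng, cfg.gen3_offspring_dist, 1)[0])
                if n_gc > 0:
                    counts["spouse"] += 1
                gc_of[child_iid] = n_gc
                married.append((child_idx, child_iid, n_gc))
                gc_fa, gc_mo = (child_idx, sp) if child_sex == MALE else (sp, child_idx)
                gc_fa_iid, gc_mo_iid = (
                    (child_iid, sp_iid) if child_sex == MALE else (sp_iid, child_iid)
                )
                gcs: list[tuple[int, str, str]] = []
                for _ in range(n_gc):
                    sex = MALE if rng.random() < 0.5 else FEMALE
                    byear = individuals[child_idx].birth_year + rng.uniform(22.0, 30.0)
                    iid = str(next_iid)
                    next_iid += 1
                    counts["father-son" if sex == MALE else "father-daughter"] += 1
                    counts["mother-son" if sex == MALE else "mother-daughter"] += 1
                    counts["grandparent"] += 2
                    counts["avuncular"] += len(children) - 1
                    gcs.append(
                        (add_person(fid, iid, gc_fa_iid, gc_mo_iid, sex, byear,
                                    gc_fa, gc_mo, 2, [(house1, lam)], -1),
                         iid, sex)
                    )
                for (_, _, sa), (_, _, sb) in _unordered_pairs(gcs):
                    if sa == sb:
                        counts["sister-sister" if sa == FEMALE else "brother-brother"] += 1
                    else:
                        counts["brother-sister"] += 1
            for (_, iid_a, na), (_, iid_b, nb) in _unordered_pairs(
                [(i, iid, n) for i, iid, n in married]
            ):
                counts["cousin"] += na * nb

    ped = Pedigree(individuals)
    return SimulatedPedigree(
        pedigree=ped,
        index=index,
        father_idx=np.asarray(fa_i, dtype=np.int64),
        mother_idx=np.asarray(mo_i, dtype=np.int64),
        level=np.asarray(level, dtype=np.int64),
        sex=np.asarray([ind.sex for ind in individuals], dtype=object),
        birth_year=np.asarray([ind.birth_year for ind in individuals], dtype=float),
        house1_idx=np.asarray(h1_idx, dtype=np.int64),
        house1_load=np.asarray(h1_load, dtype=float),
        house2_idx=np.asarray(h2_idx, dtype=np.int64),
        house2_load=np.asarray(h2_load, dtype=float),
        n_households=n_house,
        couple_idx=np.asarray(couple_i, dtype=np.int64),
        n_couples=n_couples,
        relation_counts=dict(counts),
    )


def _unordered_pairs(items):
    for i, a in enumerate(items):
        for b in items[i + 1:]:
            yield a, b


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------


def simulate_latent(
    sim: SimulatedPedigree, cfg: SimConfig, h2: float, rng: np.random.Generator
) -> np.ndarray:
    """One latent N(0,1) trait vector with the configured familial structure.

    Additive-genetic part by gene dropping: founder breeding values are
    N(0, h2); each offspring receives the midparent value plus a Mendelian
    segregation deviate N(0, h2/2) (outbred parents).  Environmental part:
    household factor(s), couple factor, independent residual.
    """
    n = sim.n
    g = np.zeros(n)
    for lev in range(int(sim.level.max()) + 1 if n else 0):
        mask = sim.level == lev
        founders = mask & (sim.father_idx < 0)
        g[founders] = rng.normal(0.0, math.sqrt(h2), founders.sum())
        kids = mask & (sim.father_idx >= 0)
        if kids.any():
            mid = 0.5 * (g[sim.father_idx[kids]] + g[sim.mother_idx[kids]])
            g[kids] = mid + rng.normal(0.0, math.sqrt(h2 / 2.0), kids.sum())

    house = rng.standard_normal(sim.n_households)
    env = math.sqrt(cfg.c_house) * (
        np.where(sim.house1_idx >= 0, sim.house1_load * house[sim.house1_idx], 0.0)
        + np.where(sim.house2_idx >= 0, sim.house2_load * house[sim.house2_idx], 0.0)
    )
    couple = rng.standard_normal(max(sim.n_couples, 1))
    in_couple = sim.couple_idx >= 0
    env = env + np.where(
        in_couple, math.sqrt(cfg.c_spouse) * couple[np.clip(sim.couple_idx, 0, None)], 0.0
    )
    load_sq = np.where(sim.house1_idx >= 0, sim.house1_load**2, 0.0) + np.where(
        sim.house2_idx >= 0, sim.house2_load**2, 0.0
    )
    resid_var = 1.0 - h2 - cfg.c_house * load_sq - cfg.c_spouse * in_couple
    resid_var = np.clip(resid_var, 0.0, None)
    return g + env + rng.standard_normal(n) * np.sqrt(resid_var)


@dataclass
class SimulatedData:
    """Per-survey records plus generator bookkeeping."""

    records: pd.DataFrame  # fid iid survey age sex energy_kcal <traits...>
    units: dict[str, str]
    latent: dict[str, np.ndarray]  # trait -> latent vector over sim.index
    outlier_mask: np.ndarray  # over record rows: energy planted out of range


def simulate_traits(
    sim: SimulatedPedigree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> SimulatedData:
    """Per-survey observed records for every configured trait.

    Observed value = mean + sd*latent + age_effect*(age - 42) + survey
    noise with SD ``survey_cv * mean``.  Each person receives 1-4 survey
    waves per ``n_surveys_dist``; the energy trait gets implausible values
    planted on an ``outlier_fraction`` subset of person-surveys.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 0xFEED]).generate_state(1)[0]
        )
    n = sim.n
    latent = {t.name: simulate_latent(sim, cfg, cfg.trait_h2(t), rng) for t in cfg.traits}

    n_surv = _sample_counts(rng, cfg.n_surveys_dist, n) + 1
    rows_person: list[int] = []
    rows_survey: list[int] = []
    waves = np.arange(FIRST_SURVEY, FIRST_SURVEY + 4)
    for i in range(n):
        chosen = np.sort(rng.choice(waves, size=n_surv[i], replace=False))
        rows_person.extend([i] * n_surv[i])
        rows_survey.extend(chosen.tolist())
    person = np.asarray(rows_person)
    survey = np.asarray(rows_survey)
    year = BASE_YEAR + SURVEY_INTERVAL_YEARS * (survey - FIRST_SURVEY)
    age = year - sim.birth_year[person]

    data = {
        "fid": [sim.index[i][0] for i in person],
        "iid": [sim.index[i][1] for i in person],
        "survey": survey,
        "age": np.round(age, 1),
        "sex": sim.sex[person],
    }
    units: dict[str, str] = {}
    outlier_mask = np.zeros(len(person), dtype=bool)
    for t in cfg.traits:
        vals = (
            t.mean
            + t.sd * latent[t.name][person]
            + cfg.trait_age_effect(t) * (age - REFERENCE_AGE)
            + rng.standard_normal(len(person)) * (cfg.survey_cv * abs(t.mean))
        )
        col = "energy_kcal" if t.name == "energy" else t.name
        if t.name == "energy":
            plant = rng.random(len(person)) < cfg.outlier_fraction
            low = rng.random(len(person)) < 0.5
            vals = np.where(
                plant,
                np.where(low, rng.uniform(300.0, 780.0, len(person)),
                         rng.uniform(4250.0, 6500.0, len(person))),
                np.clip(vals, 50.0, None),  # energy must stay positive
            )
            outlier_mask = plant
        data[col] = np.round(vals, 2)
        units[col] = t.unit
    records = pd.DataFrame(data)
    return SimulatedData(records=records, units=units, latent=latent,
                         outlier_mask=outlier_mask)


# ---------------------------------------------------------------------------
# Analytic pair covariances (oracle for tests)
# ---------------------------------------------------------------------------


def expected_pair_covariance(
    cfg: SimConfig, relation: str, trait: TraitSpec | None = None
) -> float:
    """Closed-form latent covariance the generator implies for a pair type.

    Exact for two-generation families (founder couple + co-resident
    offspring): spouse = c_house + c_spouse; parent-offspring = h2/2 +
    lambda*c_house; full siblings = h2/2 + lambda^2*c_house.  Second-degree
    relations only arise in three-generation families where the relevant
    dyads share no household factor, so they are genetic-only.  Pass a
    ``TraitSpec`` to scale to trait units (multiplied by sd^2).
    """
    lam = cfg.household_attenuation
    h2 = cfg.h2 if trait is None or trait.h2 is None else trait.h2
    values = {
        "spouse": cfg.c_house + cfg.c_spouse,
        "father-son": h2 / 2 + lam * cfg.c_house,
        "father-daughter": h2 / 2 + lam * cfg.c_house,
        "mother-son": h2 / 2 + lam * cfg.c_house,
        "mother-daughter": h2 / 2 + lam * cfg.c_house,
        "parent-offspring": h2 / 2 + lam * cfg.c_house,
        "sister-sister": h2 / 2 + lam**2 * cfg.c_house,
        "brother-brother": h2 / 2 + lam**2 * cfg.c_house,
        "brother-sister": h2 / 2 + lam**2 * cfg.c_house,
        "sibling": h2 / 2 + lam**2 * cfg.c_house,
        "half-sibling": h2 / 4 + lam**2 * cfg.c_house,
        "grandparent": h2 / 4,
        "avuncular": h2 / 4,
        "cousin": h2 / 8,
        "unrelated": 0.0,
    }
    if relation not in values:
        raise KeyError(f"unknown relation {relation!r}")
    scale = 1.0 if trait is None else trait.sd**2
    return values[relation] * scale


# ---------------------------------------------------------------------------
# Gene-dropping Monte Carlo kinship (independent oracle for the recursion)
# ---------------------------------------------------------------------------


def monte_carlo_kinship(
    ped: Pedigree,
    fid: str,
    n_drops: int = 100_000,
    rng: np.random.Generator | None = None,
    chunk: int = 200_000,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Estimate kinship coefficients for one family by allele dropping.

    Each drop assigns two distinct allele labels to every founder (and to
    each unknown-parent slot) and transmits a uniformly chosen parental
    allele to each offspring.  phi(i,j) is estimated as the mean over drops
    of the fraction of the four cross-individual allele comparisons that
    are identical by descent; phi(i,i) uses the same formula with
    replacement, giving 0.5*(1 + F_i) in expectation.

    Returns (iids, phi_hat, phi_se) with Monte-Carlo standard errors.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    order = ped.topological_order(fid)
    idx = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    fa = np.full(n, -1)
    mo = np.full(n, -1)
    for k, iid in enumerate(order):
        ind = ped.get(fid, iid)
        if ind.father is not None:
            fa[k] = idx[ind.father]
        if ind.mother is not None:
            mo[k] = idx[ind.mother]

    sums = np.zeros((n, n))
    sqsums = np.zeros((n, n))
    done = 0
    label = 0
    # constant labels for real founders; unknown-parent slots get their own
    founder_alleles = np.zeros((n, 2), dtype=np.int64)
    for k in range(n):
        founder_alleles[k] = (2 * k, 2 * k + 1)
    missing_base = 2 * n  # allele labels for unknown-parent contributions

    while done < n_drops:
        r = min(chunk, n_drops - done)
        alleles = np.empty((n, 2, r), dtype=np.int32)
        label = missing_base
        for k in range(n):
            if fa[k] < 0 and mo[k] < 0:
                alleles[k, 0] = founder_alleles[k, 0]
                alleles[k, 1] = founder_alleles[k, 1]
                continue
            for slot, parent in enumerate((fa[k], mo[k])):
                if parent < 0:
                    # unknown unrelated founder: fixed private allele
                    alleles[k, slot] = label
                    label += 1
                else:
                    pick = rng.integers(0, 2, r)
                    alleles[k, slot] = alleles[parent, pick, np.arange(r)]
        for i in range(n):
            for j in range(i + 1):
                m = np.zeros(r)
                for a in range(2):
                    for b in range(2):
                        m += alleles[i, a] == alleles[j, b]
                m *= 0.25
                sums[i, j] += m.sum()
                sqsums[i, j] += (m * m).sum()
        done += r

    phi = sums / n_drops
    var = np.clip(sqsums / n_drops - phi**2, 0.0, None)
    se = np.sqrt(var / n_drops)
    phi = phi + phi.T - np.diag(np.diag(phi))  # mirror lower triangle
    se = se + se.T - np.diag(np.diag(se))
    return order, phi, se


# ---------------------------------------------------------------------------
# File output (same formats the pipeline reads)
# ---------------------------------------------------------------------------


def write_simulated(sim: SimulatedPedigree, data: SimulatedData, outdir) -> dict[str, str]:
    """Write PED + wide trait TSV + units JSON; returns path map."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    ped_path = os.path.join(outdir, "sim.ped")
    traits_path = os.path.join(outdir, "surveys.tsv")
    units_path = os.path.join(outdir, "units.json")
    sim.pedigree.to_ped(ped_path)
    data.records.to_csv(traits_path, sep="\t", index=False)
    with open(units_path, "w") as fh:
        json.dump(data.units, fh, indent=1, sort_keys=True)
    return {"ped": ped_path, "surveys": traits_path, "units": units_path}


def simulate_dataset(cfg: SimConfig) -> tuple[SimulatedPedigree, SimulatedData]:
    """Pedigree + trait records from one seed (single entry point)."""
    rng = np.random.default_rng(cfg.seed)
    sim = simulate_pedigree(cfg, rng)
    data = simulate_traits(sim, cfg, rng)
    return sim, data
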