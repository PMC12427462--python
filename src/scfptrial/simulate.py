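"""Synthetic feeding-trial cohort generator.

Emulates the design of a three-arm SCFP feline trial: 63 cats (21 per
arm: control CD, and two supplementation levels T150/T300 at 150 and
300 mg/kg body weight) sampled at days 0, 21 and 42; species-rank
shotgun profiles with log-normal base abundances, cat-level composition
noise and heterogeneous multinomial sequencing depth; genome annotations
with butyrate routes planted in a subset of producer species; two-bowl
palatability panels with a configurable preference effect; and per-cat
digestibility records.

Planted structure (recorded in ``TrialBundle.truth`` so recovery can be
scored):

* the control arm receives a progressive power-tilt of each cat's
  composition, numerically calibrated so the composition-level Shannon
  index declines linearly by ``shannon_decline_slope`` per timepoint step;
* selected producer species receive linear log-abundance trends in one
  arm;
* each producer species has at least one genome carrying a complete
  butyrate route (and the first producer deliberately has two genomes of
  which only one carries the route, exercising the any-genome rule).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .butyrate import ButyratePathwayCatalog
from .io import (AbundanceTable, DigestibilityRecord, GenomeAnnotation,
                 PalatabilityRecord, TrialDesign, ValidationError,
                 write_abundance_table, write_genome_annotations,
                 write_result_table)

__all__ = ["CohortConfig", "TrialBundle", "generate_trial", "ration_kcal"]


def ration_kcal(body_weight_kg: float) -> float:
    """Daily maintenance energy ration: 100 x (BW kg)^0.67 kcal/day."""
    if body_weight_kg <= 0:
        raise ValidationError("body weight must be positive")
    return 100.0 * body_weight_kg ** 0.67


def _default_preferences() -> dict:
    # logit shifts toward the second diet of each pair; magnitudes are the
    # natural logs of the trial's observed consumption ratios, so the
    # expected consumption ratios reproduce those conditions
    return {
        ("CD", "T150"): math.log(1.72),
        ("CD", "T300"): math.log(2.35),
        ("T150", "T300"): -math.log(1.42),
    }


def _default_attd() -> dict:
    return {"dry_matter": 81.61, "protein": 82.69, "fat": 84.64, "energy": 84.40}


@dataclass
class CohortConfig:
    """All knobs of the synthetic trial; defaults are the study conditions."""

    n_cats_per_arm: int = 21
    arms: dict = field(default_factory=lambda: {"CD": 0, "T150": 150, "T300": 300})
    timepoint_days: tuple = (0, 21, 42)
    n_species: int = 560
    n_genera: int = 198
    depth_range: tuple = (89_217, 1_527_695)
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    cat_sigma: float = 0.6          # sd of per-cat log-abundance noise
    shannon_decline_slope: float = -0.07  # control arm, per timepoint step
    planted_trend_taxa: dict | None = None  # taxon -> (diet, log-slope/step)
    n_planted_trends: int = 5
    planted_trend_slope: float = 0.4
    planted_trend_arm: str = "T300"
    n_butyrate_producers: int = 30
    route_carrier_share: float = 0.6
    pal_n_cats: int = 20
    pal_offered_g: float = 100.0
    pal_base_fraction: float = 0.33  # mean per-bowl share of offered food eaten
    pal_concentration: float = 8.0   # Beta concentration of bowl fractions
    pal_abstain_prob: float = 0.03
    preference_effects: dict = field(default_factory=_default_preferences)
    attd_targets: dict = field(default_factory=_default_attd)
    seed: int = 0

    def __post_init__(self):
        if self.n_butyrate_producers > self.n_species:
            raise ValidationError("more butyrate producers than species")
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] <= 0:
            raise ValidationError("invalid depth range")
        for f in ("n_cats_per_arm", "n_species", "n_genera", "pal_n_cats"):
            if getattr(self, f) <= 0:
                raise ValidationError(f"{f} must be positive")
        if len(set(self.arms.values())) != len(self.arms):
            raise ValidationError("arms must map to distinct doses")
        if self.n_planted_trends > self.n_butyrate_producers:
            raise ValidationError("more planted trends than producers")


@dataclass
class TrialBundle:
    """A complete synthetic trial plus the planted truth."""

    abundance: AbundanceTable
    annotations: list[GenomeAnnotation]
    design: TrialDesign
    palatability: list[PalatabilityRecord]
    digestibility: list[DigestibilityRecord]
    genus_map: dict
    truth: dict

    def palatability_pair(self, diet_a: str, diet_b: str) -> list[PalatabilityRecord]:
        return [r for r in self.palatability
                if {r.diet_a, r.diet_b} == {diet_a, diet_b}]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_abundance_table(self.abundance, out / "abundance_species.tsv")
        write_genome_annotations(self.annotations, out / "annotations.tsv")
        write_result_table(self.design.rows, out / "design.tsv")
        pal = pd.DataFrame([vars(r) for r in self.palatability])
        write_result_table(pal, out / "palatability.tsv")
        dig = pd.DataFrame([vars(r) for r in self.digestibility])
        write_result_table(dig, out / "digestibility.tsv")
        gm = pd.DataFrame(sorted(self.genus_map.items()),
                          columns=["species_id", "genus_id"])
        write_result_table(gm, out / "genus_map.tsv")
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _shannon_prop(p: np.ndarray) -> float:
    q = p[p > 0]
    return float(-(q * np.log(q)).sum())


def _tilt_to_target(p: np.ndarray, target_h: float) -> np.ndarray:
    """Power-tilt p -> p^(1+eps)/Z with eps solved so Shannon hits target."""

    def f(eps):
        q = p ** (1.0 + eps)
        q = q / q.sum()
        return _shannon_prop(q) - target_h

    if abs(f(0.0)) < 1e-12:
        return p
    lo, hi = -0.9, 1.0
    while f(hi) > 0 and hi < 64:
        hi *= 2
    eps = brentq(f, lo, hi, xtol=1e-10)
    q = p ** (1.0 + eps)
    return q / q.sum()


def _random_ec(rng) -> str:
    return ".".join(str(rng.integers(1, 40)) for _ in range(4))


def _decoy_ecs(rng, pool: list[str]) -> set[str]:
    """EC sets guaranteed NOT to complete any butyrate route."""
    ecs = set(rng.choice(pool, size=rng.integers(3, 9), replace=False))
    # partial route fragments to make the screen non-trivial
    if rng.random() < 0.3:
        ecs.add("1.3.1.86")       # one terminal reductase only
    if rng.random() < 0.3:
        ecs.add(str(rng.choice(["2.8.3.12", "4.1.1.70"])))  # one glutarate gene
    if rng.random() < 0.3:
        ecs |= set(rng.choice(["1.1.1.6", "4.2.1.120", "5.3.3.3"],
                              size=rng.integers(1, 3), replace=False))
        if {"1.1.1.6", "4.2.1.120", "5.3.3.3"} <= ecs:
            ecs.discard("5.3.3.3")
    return ecs


def _make_annotations(rng, species_ids, producers, catalog, cfg) -> list[GenomeAnnotation]:
    decoy_pool = sorted({_random_ec(rng) for _ in range(60)} -
                        {ec for r in catalog.routes for ec in r.required_ecs})
    ko_pool = [f"K{n:05d}" for n in rng.choice(np.arange(10000, 99999), 60, replace=False)]
    ko_pool = sorted(set(ko_pool) - set(catalog.terminal_kos.values()))
    pw_pool = [f"ko{n:05d}" for n in range(100, 120)]
    cazy_pool = [f"GH{n}" for n in range(1, 26)] + [f"GT{n}" for n in range(1, 6)]
    terminal_kos = sorted(catalog.terminal_kos.values())

    producers = list(producers)
    annotations = []
    for sp in species_ids:
        is_producer = sp in producers
        if is_producer and sp == producers[0]:
            n_genomes, carriers = 2, [True, False]  # any-genome rule exercised
        elif is_producer:
            n_genomes = int(rng.integers(1, 4))
            carriers = list(rng.random(n_genomes) < cfg.route_carrier_share)
            if not any(carriers):
                carriers[int(rng.integers(n_genomes))] = True
        else:
            n_genomes = int(rng.integers(1, 3))
            carriers = [False] * n_genomes
        route = catalog.routes[int(rng.integers(len(catalog.routes)))]
        for g in range(n_genomes):
            ecs = _decoy_ecs(rng, decoy_pool)
            kos = set(rng.choice(ko_pool, size=rng.integers(5, 16), replace=False))
            if carriers[g]:
                ecs |= set(route.required_ecs)
                kos |= set(rng.choice(terminal_kos,
                                      size=rng.integers(1, len(terminal_kos) + 1),
                                      replace=False))
            annotations.append(GenomeAnnotation(
                genome_id=f"{sp}_g{g + 1}", species_id=sp,
                ec_numbers=frozenset(ecs), kegg_kos=frozenset(kos),
                kegg_pathways=frozenset(rng.choice(pw_pool, size=rng.integers(2, 7),
                                                   replace=False)),
                cazy_families=frozenset(rng.choice(cazy_pool, size=rng.integers(1, 6),
                                                   replace=False))))
    return annotations


def _make_palatability(rng, cfg) -> list[PalatabilityRecord]:
    records = []
    m0 = cfg.pal_base_fraction
    kappa = cfg.pal_concentration
    for (diet_a, diet_b), effect in sorted(cfg.preference_effects.items()):
        pb = 1.0 / (1.0 + math.exp(-effect))       # P(prefer diet_b)
        mean_b = 2 * m0 * pb
        mean_a = 2 * m0 * (1 - pb)
        for i in range(cfg.pal_n_cats):
            for day in (1, 2):
                fa = rng.beta(mean_a * kappa, (1 - mean_a) * kappa)
                fb = rng.beta(mean_b * kappa, (1 - mean_b) * kappa)
                if rng.random() < cfg.pal_abstain_prob:
                    choice = "none"
                else:
                    choice = diet_b if rng.random() < pb else diet_a
                records.append(PalatabilityRecord(
                    cat_id=f"pcat{i + 1:02d}", day=day,
                    diet_a=diet_a, diet_b=diet_b,
                    grams_a=round(fa * cfg.pal_offered_g, 1),
                    grams_b=round(fb * cfg.pal_offered_g, 1),
                    first_choice=choice, offered_g=cfg.pal_offered_g))
    return records


_NUTRIENT_INTAKE = {"dry_matter": 60.0, "protein": 20.0, "fat": 10.0, "energy": 280.0}


def _make_digestibility(rng, cat_ids, cfg) -> list[DigestibilityRecord]:
    records = []
    for cat in cat_ids:
        for nutrient, target in sorted(cfg.attd_targets.items()):
            base = _NUTRIENT_INTAKE.get(nutrient, 50.0)
            intake = max(float(rng.normal(base, 0.1 * base)), 0.1 * base)
            digest = np.clip(rng.normal(target, 1.5), 0.0, 100.0)
            output = intake * (1.0 - digest / 100.0)
            records.append(DigestibilityRecord(
                cat_id=cat, nutrient=nutrient,
                intake_g_per_day=round(intake, 3),
                fecal_output_g_per_day=round(float(output), 3)))
    return records


def generate_trial(config: CohortConfig | None = None) -> TrialBundle:
    """Generate a complete synthetic trial bundle, deterministic per seed."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    catalog = ButyratePathwayCatalog()

    width = max(4, len(str(cfg.n_species)))
    species_ids = [f"sp{i + 1:0{width}d}" for i in range(cfg.n_species)]
    genus_ids = [f"g{i % cfg.n_genera + 1:03d}" for i in range(cfg.n_species)]
    genus_map = dict(zip(species_ids, genus_ids))

    producers = sorted(rng.choice(species_ids, size=cfg.n_butyrate_producers,
                                  replace=False))
    if cfg.planted_trend_taxa is None:
        trend_taxa = sorted(rng.choice(producers, size=cfg.n_planted_trends,
                                       replace=False))
        s = cfg.planted_trend_slope
        # mirror the observed pattern: more decliners than risers (3:2)
        n_down = max(1, round(cfg.n_planted_trends * 0.6))
        slopes = [-s] * n_down + [s] * (cfg.n_planted_trends - n_down)
        planted = {t: (cfg.planted_trend_arm, sl) for t, sl in zip(trend_taxa, slopes)}
    else:
        planted = dict(cfg.planted_trend_taxa)

    base_log = rng.normal(cfg.lognormal_mu, cfg.lognormal_sigma, cfg.n_species)
    sp_index = {s: i for i, s in enumerate(species_ids)}
    for taxon in planted:
        base_log[sp_index[taxon]] = max(base_log[sp_index[taxon]],
                                        cfg.lognormal_mu + 1.5 * cfg.lognormal_sigma)

    # cats, arms, sex, weight
    arms = sorted(cfg.arms.items(), key=lambda kv: kv[1])
    n_cats = cfg.n_cats_per_arm * len(arms)
    cat_ids = [f"cat{i + 1:02d}" for i in range(n_cats)]
    order = rng.permutation(n_cats)
    diet_of = {}
    for k, (diet, _dose) in enumerate(arms):
        for idx in order[k * cfg.n_cats_per_arm:(k + 1) * cfg.n_cats_per_arm]:
            diet_of[cat_ids[idx]] = diet
    n_female = int(round(n_cats * 38 / 63))
    sexes = np.array(["F"] * n_female + ["M"] * (n_cats - n_female))
    rng.shuffle(sexes)
    sex_of = dict(zip(cat_ids, sexes))
    weight_of = {c: float(np.clip(rng.normal(4.4, 0.7), 2.64, 6.35)) for c in cat_ids}

    # abundance matrix
    design_rows = []
    count_rows = {}
    for cat in cat_ids:
        cat_log = base_log + rng.normal(0.0, cfg.cat_sigma, cfg.n_species)
        p0 = np.exp(cat_log)
        p0 = p0 / p0.sum()
        h0 = _shannon_prop(p0)
        diet = diet_of[cat]
        for step, day in enumerate(cfg.timepoint_days):
            p = p0
            if diet == "CD" and cfg.shannon_decline_slope != 0 and step > 0:
                p = _tilt_to_target(p0, h0 + cfg.shannon_decline_slope * step)
            if step > 0:
                boost = np.zeros(cfg.n_species)
                touched = False
                for taxon, (arm, slope) in planted.items():
                    if arm == diet:
                        boost[sp_index[taxon]] = slope * step
                        touched = True
                if touched:
                    p = p * np.exp(boost)
                    p = p / p.sum()
            depth = int(rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1))
            counts = rng.multinomial(depth, p)
            sample_id = f"{cat}_d{day:02d}"
            count_rows[sample_id] = counts
            design_rows.append({
                "cat_id": cat, "sex": sex_of[cat], "diet": diet,
                "dose_mg_per_kg": cfg.arms[diet], "timepoint_day": day,
                "body_weight_kg": round(weight_of[cat], 2), "sample_id": sample_id})

    counts_df = pd.DataFrame.from_dict(count_rows, orient="index",
                                       columns=species_ids)
    abundance = AbundanceTable(counts_df, rank="species")
    design = TrialDesign(pd.DataFrame(design_rows))

    annotations = _make_annotations(rng, species_ids, producers, catalog, cfg)
    palatability = _make_palatability(rng, cfg)
    digestibility = _make_digestibility(rng, cat_ids, cfg)

    truth = {
        "seed": cfg.seed,
        "producer_species": producers,
        "planted_trends": {t: {"diet": d, "slope_per_step": s}
                           for t, (d, s) in sorted(planted.items())},
        "shannon_decline_slope": cfg.shannon_decline_slope,
        "preference_effects": {f"{a}|{b}": e
                               for (a, b), e in sorted(cfg.preference_effects.items())},
        "attd_targets": dict(sorted(cfg.attd_targets.items())),
    }
    return TrialBundle(abundance=abundance, annotations=annotations, design=design,
                       palatability=palatability, digestibility=digestibility,
                       genus_map=genus_map, truth=truth)
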