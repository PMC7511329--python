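"""Synthetic study generator emulating the piglet play-fighting design.

The generated population mirrors the study layout: 22 litters over two
farrowing batches housed as 10 control pens (one litter each) and 6
socialised pens (two litters each), litter sizes ~ Normal(10.8, 1.65).
Per-dyad play-initiation counts are Poisson with a log-rate combining a
baseline bout rate, lognormal per-animal sociability frailties (which tune
how centralised pen networks are), a littermate affinity multiplier active
only in socialised pens, and a per-male play multiplier.  The initiator of
each bout is drawn by relative sociability and reciprocation is Bernoulli.

Skin lesions are negative-binomial counts whose log-mean depends on the
animal's *true* network traits (normalised in-degree for the dyadic
contest, degree x socialisation for the 3-week response) and its latent
attack latency, so the downstream mixed models have known coefficients to
recover.  Attack latency is lognormal, right-censored at the 300 s test
ceiling (censored animals are recorded as missing, as when no attack
occurred).  A truth record carries every latent parameter and trait.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .centrality import degree
from .netbuild import Animal, InteractionEvent, NetworkVariant, build_network

__all__ = ["LesionModel", "SyntheticConfig", "generate", "events_frame", "animals_frame"]

ATTACK_LATENCY_CEILING_S = 300.0
OBSERVATION_DAYS = 6


@dataclass(frozen=True)
class LesionModel:
    """Log-scale coefficients of the lesion-generating process.

    ``beta_intercept`` is the log mean contest lesion gain for a baseline
    animal; the 24 h and 3-week responses use fixed offsets from it that
    match the relative magnitudes seen in grower pigs (roughly 40 contest
    / 70 at 24 h / 20 fresh at 3 weeks).  ``beta_attack_latency`` is per
    second of latent attack latency; ``beta_in_degree`` per unit of
    normalised binary in-degree (contest response); and
    ``beta_degree_x_treatment`` per unit of normalised degree in
    socialised animals only (3-week response).  ``dispersion`` is the
    negative-binomial size parameter (smaller = more overdispersed).
    """

    beta_intercept: float = math.log(40.0)
    beta_attack_latency: float = -0.002
    beta_in_degree: float = -1.0
    beta_degree_x_treatment: float = 0.75
    dispersion: float = 3.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_control_pens: int = 10
    n_socialised_pens: int = 6
    litter_size_mean: float = 10.8
    litter_size_sd: float = 1.65
    sex_ratio: float = 0.5
    male_play_multiplier: float = 1.5
    base_bout_rate: float = 0.55  # expected reciprocated bouts per baseline dyad
    # in a reference pen of litter_size_mean animals; dyad rates scale with
    # (litter_size_mean - 1)/(pen size - 1) so per-animal play is roughly
    # pen-size invariant (piglets cap their total play, so doubling the
    # available partners does not double the interactions)
    reciprocation_prob: float = 0.7
    littermate_affinity: float = 2.0  # rate multiplier, littermate dyads in socialised pens
    centralisation_skew: float = 0.6  # sd of log-normal sociability frailty
    lesion_model: LesionModel = field(default_factory=LesionModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_control_pens < 0 or self.n_socialised_pens < 0:
            raise ValueError("pen counts must be nonnegative")
        if self.n_control_pens + self.n_socialised_pens == 0:
            raise ValueError("at least one pen is required")
        for name in (
            "litter_size_mean",
            "base_bout_rate",
            "littermate_affinity",
            "centralisation_skew",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.male_play_multiplier <= 0:
            raise ValueError("male_play_multiplier must be positive")
        if not 0 <= self.reciprocation_prob <= 1:
            raise ValueError("reciprocation_prob must be in [0, 1]")
        if not 0 < self.sex_ratio < 1:
            raise ValueError("sex_ratio must be in (0, 1)")


def _nb(rng: np.random.Generator, mean, dispersion: float):
    """Negative binomial draw(s) with mean ``mean`` and size ``dispersion``."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def generate(config: SyntheticConfig):
    """Draw one synthetic study.

    Returns ``(events, animals, truth)``: the scored initiation events,
    the animal metadata (lesions, latencies, weights, contest dyads and
    mixing pens filled in) and a truth record holding the generator
    parameters and each animal's latent sociability, latency and true
    network traits.  Identical seeds give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lm = config.lesion_model

    # --- pens, litters, animals -------------------------------------------
    pen_specs = []  # (pen_id, treatment, batch, [litter ids])
    litter_counter = 0
    n_pens = config.n_control_pens + config.n_socialised_pens
    kinds = ["control"] * config.n_control_pens + ["socialised"] * config.n_socialised_pens
    for k, kind in enumerate(kinds):
        batch = 1 if k % 2 == 0 else 2
        n_lit = 2 if kind == "socialised" else 1
        litters = [f"L{litter_counter + i + 1:02d}" for i in range(n_lit)]
        litter_counter += n_lit
        pen_specs.append((f"pen{k + 1:02d}", kind, batch, litters))

    animals_raw = []  # dicts, later converted to Animal
    for pen_id, kind, batch, litters in pen_specs:
        for litter_id in litters:
            size = max(3, int(round(rng.normal(config.litter_size_mean, config.litter_size_sd))))
            for _ in range(size):
                aid = f"a{len(animals_raw) + 1:03d}"
                animals_raw.append(
                    {
                        "id": aid,
                        "pen_id": pen_id,
                        "litter_id": litter_id,
                        "sex": "male" if rng.random() < config.sex_ratio else "female",
                        "treatment": kind,
                        "batch": batch,
                        "sociability": float(rng.normal(0.0, config.centralisation_skew)),
                    }
                )
    by_pen: dict[str, list[dict]] = {}
    for a in animals_raw:
        by_pen.setdefault(a["pen_id"], []).append(a)

    # --- play-fight initiations -------------------------------------------
    events: list[InteractionEvent] = []
    recip_rate = config.base_bout_rate / max(config.reciprocation_prob, 1e-12)
    for pen_id, kind, batch, litters in pen_specs:
        members = by_pen[pen_id]
        # play-budget ceiling: per-animal expected bouts do not grow with pen size
        size_scale = max(config.litter_size_mean - 1.0, 1.0) / max(len(members) - 1, 1)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ai, aj = members[i], members[j]
                lam = recip_rate * size_scale * math.exp(ai["sociability"] + aj["sociability"])
                if kind == "socialised" and ai["litter_id"] == aj["litter_id"]:
                    lam *= config.littermate_affinity
                lam *= config.male_play_multiplier ** (
                    (ai["sex"] == "male") + (aj["sex"] == "male")
                )
                n_bouts = rng.poisson(lam)
                if n_bouts == 0:
                    continue
                p_i = math.exp(ai["sociability"]) / (
                    math.exp(ai["sociability"]) + math.exp(aj["sociability"])
                )
                for _ in range(n_bouts):
                    init, recip = (ai, aj) if rng.random() < p_i else (aj, ai)
                    events.append(
                        InteractionEvent(
                            pen_id=pen_id,
                            day=int(rng.integers(1, OBSERVATION_DAYS + 1)),
                            initiator_id=init["id"],
                            recipient_id=recip["id"],
                            reciprocated=bool(rng.random() < config.reciprocation_prob),
                        )
                    )
    events.sort(key=lambda e: (e.pen_id, e.day))

    # --- true network traits ----------------------------------------------
    plain_animals = [
        Animal(
            id=a["id"], pen_id=a["pen_id"], litter_id=a["litter_id"],
            sex=a["sex"], treatment=a["treatment"], batch=a["batch"],
        )
        for a in animals_raw
    ]
    true_traits: dict[str, dict] = {}
    for pen_id, kind, batch, litters in pen_specs:
        net = build_network(events, plain_animals, pen_id, NetworkVariant(directed=True, weighted=False))
        indeg = degree(net, "in", weighted=False, normalise=True).values
        deg = degree(net, "all", weighted=False, normalise=True).values
        for aid in net.nodes:
            true_traits[aid] = {"in_degree_binary": indeg[aid], "degree_binary": deg[aid]}

    # --- latencies, lesions, weights --------------------------------------
    for a in animals_raw:
        latent_latency = float(rng.lognormal(math.log(60.0), 0.9))
        a["latent_latency"] = latent_latency
        a["attack_latency_s"] = (
            None if latent_latency >= ATTACK_LATENCY_CEILING_S else latent_latency
        )
        tt = true_traits[a["id"]]
        is_soc = a["treatment"] == "socialised"
        eta_contest = (
            lm.beta_intercept
            + lm.beta_attack_latency * latent_latency
            + lm.beta_in_degree * tt["in_degree_binary"]
        )
        eta_24h = lm.beta_intercept + math.log(70.0 / 40.0) + lm.beta_attack_latency * latent_latency
        eta_3wk = (
            lm.beta_intercept
            + math.log(20.0 / 40.0)
            + lm.beta_degree_x_treatment * tt["degree_binary"] * is_soc
        )
        pre_contest = int(_nb(rng, 5.0, lm.dispersion))
        pre_mix = int(_nb(rng, 5.0, lm.dispersion))
        a["lesions"] = {
            "pre_contest": pre_contest,
            "post_contest": pre_contest + int(_nb(rng, math.exp(eta_contest), lm.dispersion)),
            "pre_mix": pre_mix,
            "mix_24h": pre_mix + int(_nb(rng, math.exp(eta_24h), lm.dispersion)),
            "mix_3wk": int(_nb(rng, math.exp(eta_3wk), lm.dispersion)),
            "soc_24h": int(_nb(rng, 10.0, lm.dispersion)),
        }
        a["weight_contest"] = float(rng.normal(22.0, 2.4))
        a["weight_11wk"] = float(rng.normal(43.6, 5.1))

    # --- contest dyads (within batch and treatment) and mixing pens -------
    for batch in (1, 2):
        for kind in ("control", "socialised"):
            pool = [a for a in animals_raw if a["batch"] == batch and a["treatment"] == kind]
            order = rng.permutation(len(pool))
            for d in range(len(pool) // 2):
                a1, a2 = pool[order[2 * d]], pool[order[2 * d + 1]]
                dyad_id = f"dyad_b{batch}{kind[0]}{d + 1:03d}"
                a1["dyad_id"] = a2["dyad_id"] = dyad_id
                a1["weight_diff_kg"] = a1["weight_contest"] - a2["weight_contest"]
                a2["weight_diff_kg"] = -a1["weight_diff_kg"]
        pool = [a for a in animals_raw if a["batch"] == batch]
        order = rng.permutation(len(pool))
        for pos, k in enumerate(order):
            pool[k]["mix_pen_id"] = f"mix_b{batch}_{pos // 12 + 1:02d}"

    animals = [
        Animal(
            id=a["id"],
            pen_id=a["pen_id"],
            litter_id=a["litter_id"],
            sex=a["sex"],
            treatment=a["treatment"],
            batch=a["batch"],
            body_weight_kg={"contest": a["weight_contest"], "wk11": a["weight_11wk"]},
            attack_latency_s=a["attack_latency_s"],
            lesion_counts=a["lesions"],
            extra={
                "dyad_id": a.get("dyad_id"),
                "weight_diff_kg": a.get("weight_diff_kg", float("nan")),
                "mix_pen_id": a["mix_pen_id"],
            },
        )
        for a in animals_raw
    ]
    truth = {
        "config": {**asdict(replace(config, lesion_model=config.lesion_model)),
                   "lesion_model": asdict(config.lesion_model)},
        "animals": {
            a["id"]: {
                "sociability": a["sociability"],
                "latent_attack_latency_s": a["latent_latency"],
                **true_traits[a["id"]],
            }
            for a in animals_raw
        },
    }
    return events, animals, truth


def events_frame(events) -> pd.DataFrame:
    """Event list as the CSV schema ``read_events`` consumes."""
    return pd.DataFrame(
        {
            "pen_id": [e.pen_id for e in events],
            "day": [e.day for e in events],
            "initiator_id": [e.initiator_id for e in events],
            "recipient_id": [e.recipient_id for e in events],
            "reciprocated": [e.reciprocated for e in events],
        }
    )


def animals_frame(animals) -> pd.DataFrame:
    """Animal metadata as the CSV schema ``read_animals`` consumes."""
    rows = []
    for a in animals:
        row = {
            "id": a.id,
            "pen_id": a.pen_id,
            "litter_id": a.litter_id,
            "sex": a.sex,
            "treatment": a.treatment,
            "batch": a.batch,
            "attack_latency_s": a.attack_latency_s,
        }
        for tp, w in a.body_weight_kg.items():
            row[f"weight_{tp}_kg"] = w
        for tp, c in a.lesion_counts.items():
            row[f"lesions_{tp}"] = c
        for k, v in (a.extra or {}).items():
            row[k] = v
        rows.append(row)
    return pd.DataFrame(rows)
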