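"""End-to-end orchestration: events -> networks -> centrality ->
centralisation -> assortment -> outcome models, with a reproducibility
manifest.

The study configuration is one YAML/dict: either paths to an event log and
animal metadata table, or a ``simulate`` block for the synthetic
generator; plus the analysis thresholds (|r| > 0.8 trait pruning, p >= 0.1
backward elimination, VIF 10, 5000 assortment permutations) which default
to the study's values.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import centrality as C
from .assortment import permutation_test, population_littermate_test
from .centralisation import pen_metrics, treatment_comparison
from .netbuild import NetworkVariant, build_all_networks, read_animals, read_events
from .outcomes import (
    ModelSpec,
    analysis_frame,
    fit_lmm,
    lrt,
    prune_correlated,
    stepwise_network_traits,
    stepwise_systematic,
)
from .synthetic import LesionModel, SyntheticConfig, animals_frame, events_frame, generate

__all__ = ["StudyConfig", "RunManifest", "individual_trait_table", "run_all"]

#: Network traits entered as lesion-model candidates, with their variants.
TRAIT_COLUMNS = (
    ("degree_binary", False, False, "degree"),
    ("in_degree_binary", True, False, "in_degree"),
    ("out_degree_binary", True, False, "out_degree"),
    ("eigenvector_binary", False, False, "eigenvector"),
    ("betweenness", False, False, "betweenness"),
    ("clustering_coefficient", False, False, "clustering_coefficient"),
    ("degree_weighted", False, True, "degree"),
    ("in_degree_weighted", True, True, "in_degree"),
    ("out_degree_weighted", True, True, "out_degree"),
    ("eigenvector_weighted", False, True, "eigenvector"),
)

MODEL_PLAN = {
    "contest_delta": {
        "fixed": ("sex", "treatment", "attack_latency_s", "weight_diff_kg"),
        "random": ("batch", "pen_id", "dyad_id"),
    },
    "mix24_delta": {
        "fixed": ("sex", "treatment", "attack_latency_s", "contest_delta", "body_weight_kg"),
        "random": ("batch", "pen_id", "mix_pen_id"),
    },
    "mix3wk_log": {
        "fixed": ("sex", "treatment", "attack_latency_s", "contest_delta", "body_weight_kg"),
        "random": ("batch", "pen_id", "mix_pen_id"),
    },
}


@dataclass
class StudyConfig:
    events_path: str | None = None
    animals_path: str | None = None
    simulate: SyntheticConfig | None = None
    n_perm: int = 5000
    seed: int = 42
    p_rule: str = "add_one"
    corr_threshold: float = 0.8
    alpha_keep: float = 0.1
    vif_threshold: float = 10.0
    lesion_transform: str = "log1p"
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            lm = sim.pop("lesion_model", None)
            sim = SyntheticConfig(
                **sim, **({"lesion_model": LesionModel(**lm)} if lm else {})
            )
        return cls(simulate=sim, **raw)

    def canonical(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "simulate"}
        if self.simulate is not None:
            from dataclasses import asdict

            d["simulate"] = asdict(self.simulate)
        return json.dumps(d, sort_keys=True, default=str)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def individual_trait_table(events, animals) -> pd.DataFrame:
    """Per-animal network trait table (one column per trait variant).

    Degree-type traits are normalised by the observed pen maximum,
    eigenvector is max-scaled, betweenness is divided by its pair count
    (n-1)(n-2)/2 and clustering lies in [0, 1], so all traits are on
    comparable scales across pens of different size.  Also carries the raw
    play-fight involvement counts used in the descriptive tables.
    """
    nets = {
        (directed, weighted): build_all_networks(events, animals, NetworkVariant(directed, weighted))
        for directed in (False, True)
        for weighted in (False, True)
    }
    records: dict[str, dict] = {a.id: {"animal_id": a.id, "pen_id": a.pen_id} for a in animals}
    for col, directed, weighted, metric in TRAIT_COLUMNS:
        for pen_id, net in nets[(directed, weighted)].items():
            if metric in ("degree", "in_degree", "out_degree"):
                direction = {"degree": "all", "in_degree": "in", "out_degree": "out"}[metric]
                values = C.degree(net, direction, weighted=weighted, normalise=True).values
            elif metric == "eigenvector":
                if net.adjacency.sum() == 0:
                    values = {n: np.nan for n in net.nodes}
                else:
                    values = C.eigenvector(net, weighted=weighted).values
            elif metric == "betweenness":
                raw = C.betweenness(net).values
                denom = (net.n - 1) * (net.n - 2) / 2 or 1
                values = {k: v / denom for k, v in raw.items()}
            else:
                values = C.clustering(net).values
            for aid, v in values.items():
                records[aid][col] = v
    # raw involvement counts (undirected, unnormalised)
    for pen_id, net in nets[(False, True)].items():
        strength = C.degree(net, "all", weighted=True, normalise=False).values
        for aid, v in strength.items():
            records[aid]["n_play_fights"] = v
    for pen_id, net in nets[(False, False)].items():
        partners = C.degree(net, "all", weighted=False, normalise=False).values
        for aid, v in partners.items():
            records[aid]["n_play_partners"] = v
    return pd.DataFrame(list(records.values())).set_index("animal_id")


def individual_comparison(traits: pd.DataFrame, animals) -> pd.DataFrame:
    """Descriptive table of individual traits by treatment: pens are the
    experimental unit, so per-pen medians of the per-animal values are
    compared with rank-sum tests (socialised vs control pens)."""
    from .centralisation import compare_treatments, _median_iqr

    treatment = {a.pen_id: a.treatment for a in animals}
    rows = []
    for col in traits.columns:
        if col == "pen_id":
            continue
        pen_median = traits.groupby("pen_id")[col].median().dropna()
        values = pen_median.to_dict()
        soc = np.array([v for p, v in values.items() if treatment[p] == "socialised"])
        con = np.array([v for p, v in values.items() if treatment[p] == "control"])
        w, u, p = compare_treatments(values, treatment)
        rows.append(
            {
                "trait": col,
                "socialised_median_iqr": _median_iqr(soc),
                "control_median_iqr": _median_iqr(con),
                "socialised_median": float(np.median(soc)),
                "control_median": float(np.median(con)),
                "W": w,
                "U": u,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def _load_inputs(config: StudyConfig):
    if config.simulate is not None:
        events, animals, truth = generate(config.simulate)
        return events, animals, truth
    if not config.events_path or not config.animals_path:
        raise ValueError("config must give either a simulate block or events/animals paths")
    animals = read_animals(config.animals_path)
    events = read_events(config.events_path, animals)
    return events, animals, None


def fit_outcome_models(data: pd.DataFrame, traits: pd.DataFrame, config: StudyConfig) -> dict:
    """The staged modelling pipeline for all three lesion responses.

    Per response: backward-eliminate systematic effects at p >= alpha,
    AIC-stepwise the pruned network traits on the fixed-effects model,
    then refit the full mixed model with the selected traits and their
    treatment interactions (interactions backward-eliminated, traits
    kept), and compare full vs trait-free ML fits with a likelihood-ratio
    test.
    """
    traits_only = traits.drop(columns=["pen_id", "n_play_fights", "n_play_partners"], errors="ignore")
    pruned, dropped = prune_correlated(traits_only, threshold=config.corr_threshold)
    merged = data.join(pruned, on="animal_id")
    results = {}
    for response, plan in MODEL_PLAN.items():
        base = ModelSpec(response, plan["fixed"], plan["random"], "REML")
        systematic = stepwise_systematic(base, merged, alpha_keep=config.alpha_keep)
        selected, vif = stepwise_network_traits(
            systematic, list(pruned.columns), merged, vif_threshold=config.vif_threshold
        )
        chosen = [t for t in selected.fixed if t not in systematic.fixed]
        final_fixed = list(selected.fixed) + [f"{t}:treatment" for t in chosen]
        final = stepwise_systematic(
            ModelSpec(response, tuple(final_fixed), plan["random"], "REML"),
            merged,
            alpha_keep=config.alpha_keep,
            protected=set(systematic.fixed) | set(chosen),
        )
        full_reml = fit_lmm(final, merged)
        # LRT of the network-trait block, ML fits on identical rows
        used = {
            part
            for term in final.fixed
            for part in term.replace("*", ":").split(":")
            if part in merged.columns
        }
        ml_rows = merged.dropna(subset=sorted(used) + list(plan["random"]))
        full_ml = fit_lmm(ModelSpec(response, final.fixed, plan["random"], "ML"), ml_rows)
        red_ml = fit_lmm(ModelSpec(response, systematic.fixed, plan["random"], "ML"), ml_rows)
        chi2, df, p = lrt(full_ml, red_ml) if chosen else (0.0, 0, 1.0)
        results[response] = {
            "systematic": systematic,
            "selected_traits": chosen,
            "vif": vif,
            "model": full_reml,
            "lrt": {"chi2": chi2, "df": df, "p": p},
            "dropped_correlated": dropped,
        }
    return results


def run_all(config: StudyConfig | str | Path) -> dict:
    """Execute every stage in dependency order; returns all stage outputs
    and a :class:`RunManifest`, writing CSV/JSON artefacts when
    ``config.out_dir`` is set."""
    if not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config)
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        events, animals, truth = _load_inputs(config)
        treatments = {a.pen_id: a.treatment for a in animals}
        labels = {a.id: a.litter_id for a in animals}

        traits = individual_trait_table(events, animals)
        pens = pen_metrics(events, animals)
        table2 = treatment_comparison(pens, treatments)
        table3 = individual_comparison(traits, animals)

        soc_pens = sorted({a.pen_id for a in animals if a.treatment == "socialised"})
        nets_w = build_all_networks(events, animals, NetworkVariant(False, True))
        nets_dw = build_all_networks(events, animals, NetworkVariant(True, True))
        assort_rows = []
        for pen_id in soc_pens:
            for weighted in (False, True):
                res = permutation_test(
                    nets_w[pen_id], labels, weighted=weighted,
                    n_perm=config.n_perm, seed=config.seed, rule=config.p_rule,
                )
                assort_rows.append(
                    {
                        "pen_id": pen_id,
                        "variant": res.variant_label,
                        "r_obs": res.r_obs,
                        "p": res.p,
                        "n_perm": res.n_perm,
                        "seed": res.seed,
                        "rule": res.rule,
                    }
                )
        assort = pd.DataFrame(assort_rows)
        population = (
            population_littermate_test({p: nets_dw[p] for p in soc_pens}, labels)
            if soc_pens
            else None
        )

        try:
            from .outcomes import play_lesion_correlation

            play_lesion = play_lesion_correlation(events, animals)
        except ValueError:
            play_lesion = None  # socialisation-day lesion counts absent

        data = analysis_frame(animals, transform=config.lesion_transform)
        models = fit_outcome_models(data, traits, config)
        captured = [str(w.message) for w in wlist]

    manifest = RunManifest(
        config_hash=hashlib.sha256(config.canonical().encode()).hexdigest(),
        seed=config.seed,
        version=_version(),
        warnings=captured,
    )
    outputs = {
        "events": events,
        "animals": animals,
        "truth": truth,
        "traits": traits,
        "pen_metrics": pens,
        "table2": table2,
        "table3": table3,
        "assortment": assort,
        "population_assortment": population,
        "play_lesion_correlation": play_lesion,
        "models": models,
        "manifest": manifest,
    }
    if config.out_dir:
        _write_outputs(Path(config.out_dir), config, outputs, manifest)
    return outputs


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("playnet")
    except PackageNotFoundError:
        return "0.0.0+local"


def _write_outputs(out: Path, config: StudyConfig, outputs: dict, manifest: RunManifest) -> None:
    out.mkdir(parents=True, exist_ok=True)
    frames = {
        "events.csv": events_frame(outputs["events"]),
        "animals.csv": animals_frame(outputs["animals"]),
        "traits.csv": outputs["traits"].reset_index(),
        "pen_metrics.csv": outputs["pen_metrics"],
        "table2.csv": outputs["table2"],
        "table3.csv": outputs["table3"],
        "assortment.csv": outputs["assortment"],
    }
    for response, res in outputs["models"].items():
        frames[f"model_{response}.csv"] = res["model"].coef_table()
    for name, df in frames.items():
        df.to_csv(out / name, index=False)
        manifest.checksums[name] = _sha256_frame(df)
    if outputs["truth"] is not None:
        (out / "truth.json").write_text(json.dumps(outputs["truth"], indent=2, sort_keys=True))
    model_report = {
        response: {
            "selected_traits": res["selected_traits"],
            "vif": res["vif"],
            "aic": res["model"].aic,
            "loglik": res["model"].loglik,
            "n": res["model"].n,
            "lrt": res["lrt"],
        }
        for response, res in outputs["models"].items()
    }
    (out / "model_report.json").write_text(json.dumps(model_report, indent=2, sort_keys=True))
    (out / "manifest.json").write_text(manifest.to_json())
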