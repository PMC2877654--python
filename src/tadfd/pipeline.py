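"""End-to-end orchestration: data -> ordination -> trait space -> null model.

A single :class:`RunConfig` (built in code or from a YAML file) drives
the whole analysis; one root seed is split into named per-stage
substreams so a run is reproducible bit for bit.  Stages execute in the
field-analysis order: acquire or simulate the three input tables,
ordinate the habitat variables and regress SR on the retained
components, build the functional dendrogram (Gower + automated linkage
selection), score observed FD per site, run the richness-controlled
null model, and compare observed against predicted FD (polynomial
redundancy test, grouped Michaelis-Menten fit, low-FD verdict).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .nullmodel import fit_mm_grouped, low_fd_verdict, null_fd_table, redundancy_test
from .ordination import ordinate
from .simulate import AssemblyScenario, TraitSpec, generate_communities, \
    generate_habitat, generate_trait_matrix
from .traitspace import LINKAGES, gower_distance, select_clustering

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

#: Fixed order in which per-stage random substreams are split off the
#: root seed; changing it would change every downstream number.
STAGE_STREAMS = ("traits", "communities", "habitat", "nullmodel", "bootstrap")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one of ``simulation`` (scenario parameters for the
    synthetic generators) and ``inputs`` (paths to trait, community and
    habitat tables) must be given.
    """

    simulation: dict | None = None
    inputs: dict | None = None
    n_reps: int = 500
    n_boot: int = 999
    alpha: float = 0.05
    linkage_candidates: tuple = LINKAGES
    retain_override: int | None = None
    p_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulation' and 'inputs' must be set")
        if self.inputs is not None:
            missing = {"traits", "communities"} - set(self.inputs)
            if missing:
                raise ValueError(f"inputs block missing paths: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "linkage_candidates" in raw:
            raw["linkage_candidates"] = tuple(raw["linkage_candidates"])
        return cls(**raw)

    def echo(self) -> dict:
        return {
            "simulation": self.simulation,
            "inputs": self.inputs,
            "n_reps": self.n_reps,
            "n_boot": self.n_boot,
            "alpha": self.alpha,
            "linkage_candidates": list(self.linkage_candidates),
            "retain_override": self.retain_override,
            "p_threshold": self.p_threshold,
            "seed": self.seed,
        }


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage '{name}' failed: {err}") from err
    return wrap


def _acquire(config: RunConfig, rngs: dict):
    if config.simulation is not None:
        simblock = dict(config.simulation)
        coupling = simblock.pop("coupling", 0.9)
        pool_size = simblock.get("pool_size", 36)
        rr = simblock.get("richness_range")
        if rr is not None:
            simblock["richness_range"] = tuple(rr)
        traits = generate_trait_matrix(TraitSpec(), pool_size=pool_size,
                                       seed=rngs["traits"])
        scenario = AssemblyScenario(**{**simblock, "pool_size": pool_size,
                                       "seed": rngs["communities"]})
        communities = generate_communities(traits, scenario)
        habitat = generate_habitat(communities, coupling=coupling,
                                   seed=rngs["habitat"])
    else:
        traits = tio.read_trait_matrix(config.inputs["traits"])
        communities = tio.read_community_table(config.inputs["communities"])
        habitat = (tio.read_habitat_table(config.inputs["habitat"])
                   if config.inputs.get("habitat") else None)
    sp_t, sp_c = set(traits.species_ids), set(communities.species_ids)
    if sp_t != sp_c:
        raise ValueError(
            "species sets of trait matrix and community table differ; "
            f"symmetric difference: {sorted(sp_t ^ sp_c)}"
        )
    return traits, communities, habitat


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute every stage and return (and optionally write) the report.

    With ``outdir`` set, all intermediate artifacts (tables, distance
    matrix, Newick dendrogram, per-site FD table) and the JSON report
    are written there.  Re-running with the same config and seed
    reproduces the report byte for byte.
    """
    rngs = {name: np.random.default_rng(child)
            for name, child in zip(
                STAGE_STREAMS, np.random.SeedSequence(config.seed).spawn(
                    len(STAGE_STREAMS)))}
    report: dict = {"config": config.echo(), "stages": {}}

    traits, communities, habitat = _stage("data")(_acquire, config, rngs)
    sr = communities.sr
    report["stages"]["data"] = {
        "n_sites": communities.n_sites,
        "pool_size": traits.n_species,
        "n_traits": traits.n_traits,
        "sr_min": int(sr.min()), "sr_max": int(sr.max()),
        "sr_mean": float(sr.mean()),
    }

    if habitat is not None:
        ord_res = _stage("ordination")(
            ordinate, habitat, sr, n_boot=config.n_boot, alpha=config.alpha,
            seed=rngs["bootstrap"], retain_override=config.retain_override,
            threshold=config.p_threshold,
        )
        pca = ord_res["pca"]
        reg = ord_res["sr_regression"]
        report["stages"]["ordination"] = {
            "variance_proportions": [round(float(p), 10) for p in pca.proportions],
            "n_retained": ord_res["n_retained"],
            "transformed_variables": ord_res["transformed_variables"],
            "significant_loadings": {
                c: sorted(pca.significant.index[pca.significant[c]])
                for c in pca.significant.columns[:max(ord_res["n_retained"], 1)]
            },
            "sr_regression": {
                "coefficients": reg.coefficients,
                "p_values": reg.p_values,
                "r_squared": reg.r_squared,
                "f_statistic": reg.f_statistic,
                "df": [reg.df_num, reg.df_den],
                "eliminated": list(map(list, reg.eliminated)),
                "retained": list(reg.retained),
            },
        }

    dist = _stage("trait_space")(gower_distance, traits)
    selection = _stage("trait_space")(select_clustering, dist,
                                      config.linkage_candidates)
    tree = selection.tree
    report["stages"]["trait_space"] = {
        "selected_linkage": selection.selected,
        "criterion": {k: round(v, 12) for k, v in selection.criterion.items()},
        "total_branch_length": round(tree.total_branch_length(), 12),
    }

    def observed_fd():
        return tree.fd_members(communities.presence.T)
    obs_fd = _stage("fd")(observed_fd)

    null = _stage("nullmodel")(null_fd_table, tree, sr, n_reps=config.n_reps,
                               seed=rngs["nullmodel"], site_ids=communities.site_ids)
    fd_rows = [
        {"site": site, "sr": int(s), "fd": round(float(o), 12),
         "predicted_fd": round(float(r.predicted_fd), 12),
         "null_sd": round(float(r.sd), 12)}
        for site, s, o, r in zip(communities.site_ids, sr, obs_fd, null.rows)
    ]
    report["stages"]["fd"] = {"n_reps": config.n_reps, "per_site": fd_rows}

    poly = _stage("redundancy")(redundancy_test, obs_fd, sr, config.alpha)
    report["stages"]["redundancy"] = {
        "r_squared_linear": poly.r_squared_linear,
        "r_squared_quadratic": poly.r_squared_quadratic,
        "quadratic_coefficient": poly.quadratic_coefficient,
        "p_quadratic": poly.p_quadratic,
        "f_linear": poly.f_linear, "df_linear": [1, poly.df_den_linear],
        "f_quadratic": poly.f_statistic, "df_quadratic": [poly.df_num, poly.df_den],
        "redundancy": poly.redundancy,
    }

    y = np.concatenate([obs_fd, null.predicted])
    s_all = np.concatenate([sr, sr])
    g = ["observed"] * len(sr) + ["predicted"] * len(sr)
    mm = _stage("mm_comparison")(fit_mm_grouped, y, s_all, g)
    verdict = low_fd_verdict(mm, alpha=config.alpha)
    report["stages"]["mm_comparison"] = {
        "fmax_observed": mm.fmax_obs, "fmax_predicted": mm.fmax_pred,
        "k_observed": mm.k_obs, "k_predicted": mm.k_pred,
        "se_delta_fmax": mm.se_delta_fmax, "se_delta_k": mm.se_delta_k,
        "t_delta_fmax": mm.t_delta_fmax, "p_delta_fmax": mm.p_delta_fmax,
        "t_delta_k": mm.t_delta_k, "p_delta_k": mm.p_delta_k,
        "df": mm.df,
    }
    report["stages"]["verdict"] = verdict

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tio.write_trait_matrix(traits, outdir / "traits.tsv")
        tio.write_community_table(communities, outdir / "communities.tsv")
        if habitat is not None:
            tio.write_habitat_table(habitat, outdir / "habitat.tsv")
        tio.write_distance_matrix(dist, outdir / "gower_distances.tsv")
        tio.write_newick(tree, outdir / "dendrogram.nwk")
        import pandas as pd
        pd.DataFrame(fd_rows).to_csv(outdir / "fd_table.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
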