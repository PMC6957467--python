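"""End-to-end pipeline: anomalies -> per-stratum fits -> scenarios -> descriptives.

Given a :class:`~anomort.config.PipelineConfig`, :func:`run_pipeline`
sequences the analysis stages, writes every artifact under the configured
output directory and records a manifest (inputs with content hashes, seed,
stages completed, per-stage timing).  A fixed seed gives byte-identical
summary outputs across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .anomaly import (
    aggregate_to_state,
    compute_anomalies,
    compute_long_term_means,
    interpolate_population,
)
from .config import PipelineConfig
from .descriptives import age_standardized_rate, stratum_counts
from .errors import AnomortError, ValidationError
from .inference import fit
from .model import ModelSpec
from .scenario import excess_deaths, excess_relative_risk, percent_change

logger = logging.getLogger("anomort")

__all__ = ["run_pipeline", "load_adjacency"]


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def load_adjacency(path: str | Path) -> nx.Graph:
    """Read a state adjacency edge list CSV (columns state_a, state_b)."""
    edges = pd.read_csv(path)
    if {"state_a", "state_b"} - set(edges.columns):
        raise ValidationError("adjacency CSV needs columns state_a, state_b")
    G = nx.Graph()
    G.add_edges_from(edges[["state_a", "state_b"]].itertuples(index=False))
    return G


def _float_csv(df: pd.DataFrame, path: Path) -> None:
    # fixed float formatting keeps reruns byte-identical
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage of the analysis; returns the artifact directory.

    Any stage failure aborts with the stage name and cause; partially
    written outputs are flagged in the manifest.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "stages": [],
        "partial": False,
    }
    for name in ("deaths", "population", "adjacency", "anomalies", "temps",
                 "county_to_state"):
        p = getattr(config, name)
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256_16": _hash_file(p)}

    stage = "load"
    try:
        t0 = time.time()
        deaths = pd.read_csv(config.deaths)
        population = pd.read_csv(config.population)
        adjacency = load_adjacency(config.adjacency)
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 3)})

        # ---- anomalies ---------------------------------------------------
        stage = "anomalies"
        t0 = time.time()
        if config.anomalies is not None:
            anoms = pd.read_csv(config.anomalies)
        else:
            temps = pd.read_csv(config.temps)
            if config.period_start is not None:
                temps = temps[temps["year"].between(config.period_start,
                                                    config.period_end)]
            means = compute_long_term_means(temps)
            anoms = compute_anomalies(temps, means)
            if config.county_to_state is not None:
                mapping = pd.read_csv(config.county_to_state)
                monthly_pop = interpolate_population(
                    population.groupby(["unit_id", "year"], as_index=False)[
                        "population"
                    ].sum()
                )
                anoms = aggregate_to_state(anoms, monthly_pop, mapping)
        _float_csv(anoms, outdir / "anomalies.csv")
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 3)})

        # ---- monthly population merged onto deaths -----------------------
        stage = "population"
        t0 = time.time()
        if "population" not in deaths.columns:
            pop_cols = [c for c in ("sex", "age_group") if c in population.columns]
            monthly_pop = interpolate_population(population)
            deaths = deaths.merge(
                monthly_pop.rename(columns={"unit_id": "state"}),
                on=["state", "year", "month"] + pop_cols,
                how="left",
                validate="m:1",
            )
            if deaths["population"].isna().any():
                raise ValidationError("death records without matching population")
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 3)})

        # ---- per-stratum fits --------------------------------------------
        stage = "fit"
        t0 = time.time()
        strat_cols = [c for c in ("injury_type", "sex", "age_group")
                      if c in deaths.columns]
        if config.strata is not None:
            strata = [tuple(s) for s in config.strata]
        else:
            strata = sorted(
                deaths[strat_cols].drop_duplicates().itertuples(index=False, name=None)
            )
            if "injury_type" in strat_cols and not config.include_other:
                i = strat_cols.index("injury_type")
                strata = [s for s in strata if s[i] != "other"]
        years = sorted(deaths["year"].unique())
        spec = ModelSpec(adjacency=adjacency, n_times=12 * len(years))
        err_by_stratum = {d: {} for d in config.deltas}
        gamma_summaries = []
        fits_meta = {}
        for j, key in enumerate(strata):
            mask = np.logical_and.reduce(
                [deaths[c] == v for c, v in zip(strat_cols, key)]
            ) if strat_cols else np.ones(len(deaths), bool)
            sub = deaths[mask]
            draws = fit(spec, sub, anoms, seed=config.seed + j,
                        **config.backend)
            g = draws.gamma()
            for d in config.deltas:
                err_by_stratum[d][key] = excess_relative_risk(g, d)
            for m in range(g.shape[1]):
                lo, hi = np.quantile(g[:, m], [0.025, 0.975])
                gamma_summaries.append(
                    key + (m + 1, float(g[:, m].mean()), float(lo), float(hi))
                )
            fits_meta[str(key)] = {
                k: draws.meta.get(k) for k in ("rhat", "x_accept", "n_draws")
            }
        gdf = pd.DataFrame(
            gamma_summaries,
            columns=strat_cols + ["month", "gamma_mean", "gamma_lo95", "gamma_hi95"],
        )
        _float_csv(gdf, outdir / "gamma.csv")
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 3),
                                   "fits": fits_meta})

        # ---- scenarios ---------------------------------------------------
        stage = "scenario"
        t0 = time.time()
        ref_year = config.reference_year or int(deaths["year"].max())
        if strat_cols:
            keys = deaths[strat_cols].apply(tuple, axis=1)
            deaths_fitted = deaths[keys.isin(set(strata))]
        else:
            deaths_fitted = deaths
        scen_rows = []
        for d in config.deltas:
            res = excess_deaths(deaths_fitted, err_by_stratum[d], delta=d,
                                reference_year=ref_year)
            for by, table in res.tables.items():
                for _, r in table.iterrows():
                    scen_rows.append((d, by, r["level"], r["mean"], r["lo95"], r["hi95"]))
            pc = percent_change(err_by_stratum[d], deaths_fitted, reference_year=ref_year)
            _float_csv(pc, outdir / f"percent_change_delta{d:g}.csv")
        scen = pd.DataFrame(
            scen_rows, columns=["delta", "grouping", "level", "mean", "lo95", "hi95"]
        )
        _float_csv(scen, outdir / "scenario.csv")
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 3)})

        # ---- descriptives ------------------------------------------------
        stage = "descriptives"
        t0 = time.time()
        if {"age_group"} <= set(deaths.columns):
            by = tuple(c for c in ("injury_type", "sex", "month") if c in deaths.columns)
            try:
                rates = age_standardized_rate(deaths, by=by)
                _float_csv(rates, outdir / "age_standardized_rates.csv")
            except ValidationError:
                # single-age synthetic data cannot be standardised to the
                # full standard; crude rates are still meaningful
                crude = deaths.groupby(list(by), as_index=False).agg(
                    deaths=("deaths", "sum"), population=("population", "sum")
                )
                crude["rate_per_100k"] = 12e5 * crude["deaths"] / crude["population"]
                _float_csv(crude, outdir / "crude_rates.csv")
        counts = stratum_counts(deaths, by=tuple(strat_cols) or ("state",))
        _float_csv(counts, outdir / "stratum_counts.csv")
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 3)})
    except Exception as e:
        manifest["partial"] = True
        manifest["failed_stage"] = stage
        manifest["error"] = str(e)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise AnomortError(f"pipeline failed at stage {stage!r}: {e}") from e

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
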