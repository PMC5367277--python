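"""End-to-end orchestration: relatedness -> model comparison -> summaries.

Mirrors the study's analysis flow for a pedigree + phenotype pair:
per-trait DIC comparison of the four variance-component models,
variance-proportion summaries under the best model, all-pairs bivariate
genetic correlations, and the per-nest Mendelian segregation scan.
Outputs are CSV tables shaped like the study's three results tables,
plus a JSON summary carrying the package version, a configuration hash,
the seed and chain diagnostics, so every run is replayable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .animal_model import (
    ModelSpec,
    diagnostics,
    fit_bivariate,
    genetic_correlation,
    trait_series,
    variance_proportions,
)
from .model_selection import compare_models
from .pedigree import Pedigree, additive_matrix, read_pedigree
from .segregation import scan_to_frame, segregation_scan
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

#: the five scored colour traits, in the study's order
DEFAULT_TRAITS = (
    "frons_yellow",
    "clypeus_yellow",
    "clypeus_black",
    "abdomen_yellow",
    "abdomen_brown",
)


@dataclass
class RunConfig:
    """Paths, trait registry and chain settings for one pipeline run."""

    pedigree_path: str
    phenotype_path: str
    out_dir: str
    traits: tuple[str, ...] = DEFAULT_TRAITS
    presence_traits: tuple[str, ...] = ("frons_yellow", "clypeus_yellow")
    iterations: int = 10_000
    burn_in: int = 3_000
    thinning: int = 7
    seed: int = 1
    min_nest_size: int = 20
    correlations: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("traits", "presence_traits"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def model_spec(self, seed_offset: int = 0) -> ModelSpec:
        return ModelSpec(
            iterations=self.iterations,
            burn_in=self.burn_in,
            thinning=self.thinning,
            seed=self.seed + seed_offset,
        )


def _read_phenotypes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"phenotype file not found: {path}")
    frame = pd.read_csv(path, dtype={"id": str, "trait": str})
    required = {"id", "trait", "score"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"phenotype CSV missing columns: {sorted(missing)}")
    frame["score"] = frame["score"].astype(int)
    return frame


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict it also writes.

    Writes into ``cfg.out_dir``: ``dic_models.csv`` (per trait x model),
    ``variance_components.csv`` (best model per trait),
    ``genetic_correlations.csv`` (all trait pairs),
    ``segregation.csv`` (per-nest Mendelian tests), ``summary.json``
    and ``pipeline.log``.  Failures in one stage are logged and flagged
    in the summary; earlier outputs are preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("haploquant")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    summary: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    t_start = time.time()
    try:
        ped = read_pedigree(cfg.pedigree_path)
        phen = _read_phenotypes(cfg.phenotype_path)
        traits = [t for t in cfg.traits if t in set(phen["trait"])]
        if not traits:
            raise ValueError(
                f"none of the configured traits {cfg.traits} are in the phenotype table"
            )
        logger.info(
            "loaded pedigree (%d individuals) and %d traits", len(ped), len(traits)
        )

        scored_ids = tuple(
            i for i in ped.females if i in set(phen["id"])
        )
        s_matrix = additive_matrix(ped, scored_ids)
        summary["stages"]["relatedness"] = {
            "n_phenotyped": len(scored_ids),
            "min_eigenvalue": s_matrix.min_eigenvalue(),
        }

        dic_rows, var_rows = [], []
        best_fits = {}
        for k, trait in enumerate(traits):
            t0 = time.time()
            scores = trait_series(phen, trait)
            sub = s_matrix.submatrix(tuple(scores.index.astype(str)))
            res = compare_models(
                scores, ped, cfg.model_spec(seed_offset=k), sub, trait=trait
            )
            tab = res.table.copy()
            tab.insert(0, "trait", trait)
            dic_rows.append(tab)
            best_fits[trait] = res.samples[res.best]
            vs = variance_proportions(res.samples[res.best])
            diag = diagnostics(res.samples[res.best])
            for comp, entry in vs.components.items():
                var_rows.append(
                    {"trait": trait, "best_model": res.best, "component": comp, **entry}
                )
            logger.info(
                "trait %s: best=%s (%.0fs), diagnostics=%s",
                trait, res.best, time.time() - t0, diag,
            )
        pd.concat(dic_rows).to_csv(out / "dic_models.csv", index=False)
        pd.DataFrame(var_rows).to_csv(out / "variance_components.csv", index=False)
        summary["stages"]["models"] = {
            t: {"best": str(rows["best_model"].iloc[0])}
            for t, rows in pd.DataFrame(var_rows).groupby("trait")
        }

        if cfg.correlations and len(traits) > 1:
            corr_rows = []
            for k, (ta, tb) in enumerate(itertools.combinations(traits, 2)):
                fit = fit_bivariate(
                    trait_series(phen, ta),
                    trait_series(phen, tb),
                    ped,
                    cfg.model_spec(seed_offset=100 + k),
                    traits=(ta, tb),
                )
                rg = genetic_correlation(fit)
                corr_rows.append(
                    {
                        "trait_a": ta,
                        "trait_b": tb,
                        "r_G_mode": rg["mode"],
                        "low": rg["low"],
                        "high": rg["high"],
                        "significant": rg["significant"],
                    }
                )
                logger.info("r_G(%s, %s) = %.3f", ta, tb, rg["mode"])
            pd.DataFrame(corr_rows).to_csv(
                out / "genetic_correlations.csv", index=False
            )
            summary["stages"]["correlations"] = {"n_pairs": len(corr_rows)}

        seg_rows = []
        for trait in cfg.presence_traits:
            if trait not in set(phen["trait"]):
                continue
            tests = segregation_scan(
                phen, ped, trait, min_n=cfg.min_nest_size, logger=logger
            )
            frame = scan_to_frame(tests)
            if not frame.empty:
                frame.insert(0, "trait_name", trait)
                seg_rows.append(frame)
        if seg_rows:
            seg = pd.concat(seg_rows)
            seg.to_csv(out / "segregation.csv", index=False)
            summary["stages"]["segregation"] = {
                "n_tests": int(len(seg)),
                "n_rejected": int((seg["classification"] == "rejected").sum()),
            }

        summary["runtime_s"] = round(time.time() - t_start, 1)
        summary["ok"] = True
    except Exception as err:
        summary["ok"] = False
        summary["error"] = str(err)
        logger.exception("pipeline failed")
        raise
    finally:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        root.removeHandler(handler)
        handler.close()
    return summary


def make_fixture(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated pedigree CSV, phenotype CSV and truth JSON.

    The truth sidecar echoes every variance component, the resolved
    thresholds, the seed and the retained liabilities, so parameter
    recovery can be checked against it without re-simulation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped, phen, truth = simulate_dataset(cfg)
    paths = {
        "pedigree": out / "pedigree.csv",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "truth.json",
    }
    ped.write_csv(paths["pedigree"])
    phen[["id", "trait", "score"]].to_csv(paths["phenotypes"], index=False)
    truth = dict(truth)
    truth["version"] = __version__
    truth["liabilities"] = {
        trait: dict(zip(sub["id"], sub["liability"].round(6)))
        for trait, sub in phen.groupby("trait")
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
    return paths
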