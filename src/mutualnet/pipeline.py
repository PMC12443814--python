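"""End-to-end analysis orchestration.

Runs, per season scope (overall / rainy / dry): richness summary, network
metrics, fixed-marginal null standardization, extinction robustness, and
sample coverage; plus trait -> role model averaging on the overall network.
All randomness fans out from one master seed; the report records the
configuration so every number is re-derivable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .coverage import network_coverage
from .extinction import robustness_table
from .io import InteractionMatrix, VisitRecord, build_matrix, matrix_summary
from .metrics import connectance, h2prime, modularity, species_metrics, wnodf
from .nullmodels import null_test_suite
from .traitmodels import fit_trait_models

log = logging.getLogger("mutualnet")


@dataclass(frozen=True)
class PipelineConfig:
    n_null: int = 1000
    n_random_orders: int = 1000
    n_restarts: int = 20
    average: str = "full"  # model-averaging flavor
    drop_empty_species: bool = True


@dataclass
class ScopeResult:
    scope: str
    richness: dict
    network: dict
    null: dict
    species: pd.DataFrame
    robustness: dict
    coverage: dict
    errors: dict[str, str] = field(default_factory=dict)


@dataclass
class AnalysisReport:
    scopes: dict[str, ScopeResult]
    trait_models: dict[str, dict]  # side -> response -> coefficient table dict
    provenance: dict
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors and all(not s.errors for s in self.scopes.values())

    def to_dict(self) -> dict:
        return {
            "scopes": {
                name: {
                    "richness": s.richness,
                    "network": s.network,
                    "null": s.null,
                    "species": s.species.reset_index().to_dict(orient="records"),
                    "robustness": s.robustness,
                    "coverage": s.coverage,
                    "errors": s.errors,
                }
                for name, s in self.scopes.items()
            },
            "trait_models": self.trait_models,
            "provenance": self.provenance,
            "errors": self.errors,
        }

    def save(self, out_dir: str | Path) -> None:
        """Write report.json plus per-table CSVs under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with (out / "report.json").open("w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)
        network_rows = []
        for name, s in self.scopes.items():
            row = {"scope": name, **s.richness, **s.network}
            for metric, res in s.null.items():
                row[f"z_{metric}"] = res["z"]
                row[f"p_upper_{metric}"] = res["p_upper"]
                row[f"p_lower_{metric}"] = res["p_lower"]
            network_rows.append(row)
        pd.DataFrame(network_rows).to_csv(out / "table1_network.csv", index=False)
        if "overall" in self.scopes:
            self.scopes["overall"].species.to_csv(out / "table2_species.csv")
        for side, per_resp in self.trait_models.items():
            rows = []
            for resp, coefs in per_resp.items():
                for var, vals in coefs.items():
                    rows.append({"response": resp, "variable": var, **vals})
            name = "table3_bird_glm.csv" if side == "birds" else "table4_plant_glm.csv"
            pd.DataFrame(rows).to_csv(out / name, index=False)


def _scope_seeds(seed: int, names: Sequence[str]) -> dict[str, np.ndarray]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: c for n, c in zip(names, children)}


def analyze_scope(
    matrix: InteractionMatrix, scope: str, config: PipelineConfig, seed: int
) -> ScopeResult:
    """All network-side stages for one seasonal slice; failures are recorded
    per stage without aborting the rest."""
    result = ScopeResult(
        scope=scope, richness={}, network={}, null={}, species=pd.DataFrame(),
        robustness={}, coverage={},
    )
    sub = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in sub]

    log.info("[%s] richness + network metrics", scope)
    result.richness = asdict(matrix_summary(matrix))
    try:
        h2 = h2prime(matrix)
        mod = modularity(matrix, n_restarts=config.n_restarts, seed=seeds[0])
        result.network = {
            "connectance": connectance(matrix),
            "wnodf": wnodf(matrix),
            "H2": h2.H2,
            "H2prime": h2.H2prime,
            "Q": mod.Q,
            "n_modules": len(set(mod.partition.values())),
        }
    except Exception as err:  # noqa: BLE001 - stage isolation is the contract
        result.errors["network"] = str(err)

    log.info("[%s] null ensemble (N=%d)", scope, config.n_null)
    try:
        suite = null_test_suite(
            matrix,
            {
                "connectance": connectance,
                "wnodf": wnodf,
                "H2prime": lambda mm: h2prime(mm).H2prime,
                "Q": lambda mm: modularity(mm, n_restarts=max(2, config.n_restarts // 4), seed=seeds[1]).Q,
            },
            n=config.n_null,
            seed=seeds[1],
        )
        result.null = {
            k: {
                "obs": r.obs, "exp_null": r.exp_null, "sd_null": r.sd_null,
                "z": r.z, "p_upper": r.p_upper, "p_lower": r.p_lower, "p_two": r.p_two,
            }
            for k, r in suite.items()
        }
    except Exception as err:  # noqa: BLE001
        result.errors["null"] = str(err)

    log.info("[%s] species metrics, robustness, coverage", scope)
    try:
        result.species = species_metrics(matrix)
    except Exception as err:  # noqa: BLE001
        result.errors["species"] = str(err)
    try:
        result.robustness = robustness_table(
            matrix, n_orders=config.n_random_orders, seed=seeds[2]
        )
    except Exception as err:  # noqa: BLE001
        result.errors["robustness"] = str(err)
    try:
        result.coverage = {
            k: {"n": c.n, "f1": c.f1, "f2": c.f2, "C_hat": c.C_hat}
            for k, c in network_coverage(matrix).items()
        }
    except Exception as err:  # noqa: BLE001
        result.errors["coverage"] = str(err)
    return result


def run_all(
    records: Sequence[VisitRecord],
    bird_traits: pd.DataFrame | None = None,
    plant_traits: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> AnalysisReport:
    """Full analysis over all season scopes present in the records."""
    config = config or PipelineConfig()
    tagged = {r.season for r in records}
    scopes = ["overall"] + [s for s in ("rainy", "dry") if s in tagged]
    seeds = _scope_seeds(seed, scopes + ["traits"])

    scope_results: dict[str, ScopeResult] = {}
    errors: dict[str, str] = {}
    for scope in scopes:
        matrix = build_matrix(records, scope=scope)
        if config.drop_empty_species:
            matrix = matrix.drop_empty_species()
        scope_seed = int(seeds[scope].generate_state(1)[0] % (2**31))
        scope_results[scope] = analyze_scope(matrix, scope, config, scope_seed)

    trait_models: dict[str, dict] = {}
    overall = build_matrix(records, scope="overall")
    sp = species_metrics(overall)
    for side, traits in (("birds", bird_traits), ("plants", plant_traits)):
        if traits is None:
            continue
        role = "bird" if side == "birds" else "plant"
        frame = sp[sp["role"] == role][["degree", "strength", "dprime"]]
        missing = set(frame.index) - set(traits.index)
        if missing:
            errors[f"traits_{side}"] = (
                f"species missing from {side} trait table: {sorted(missing)}"
            )
            continue
        try:
            fitted = fit_trait_models(frame, traits, average=config.average)
            trait_models[side] = {
                resp: res.coefficients.to_dict(orient="index")
                for resp, res in fitted.items()
            }
        except Exception as err:  # noqa: BLE001
            errors[f"traits_{side}"] = str(err)

    provenance = {
        "version": __version__,
        "seed": seed,
        "config": asdict(config),
        "n_records": len(records),
        "scopes": scopes,
    }
    return AnalysisReport(
        scopes=scope_results, trait_models=trait_models,
        provenance=provenance, errors=errors,
    )
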