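"""Synthetic data with planted structure for end-to-end recovery tests.

The essentiality generator uses a Gaussian single-factor model per module:
each module has a latent activity per cell line drawn from N(0, 1), member
genes load on it with coefficient ``beta`` plus N(0, sigma) noise, and
background genes are pure noise. Under this model the expected within-module
Pearson correlation is ``beta**2 / (beta**2 + sigma**2)`` — e.g. 0.8 at
beta = 1, sigma = 0.5 — which is what a CLR network construction should turn
into dense within-module links.

Drivers are planted inside one designated module per cancer type; effective
drugs draw their associated genes from the driver module while null drugs
draw random genes; drug response and patient expression/survival tables are
generated with tunable effect sizes so both signal recovery and null
calibration are testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticTruth",
    "simulate_essentiality",
    "simulate_drivers",
    "simulate_drug_table",
    "simulate_response",
    "simulate_expression_survival",
]

from .netconstruct import EssentialityMatrix


@dataclass
class SyntheticTruth:
    """Planted ground truth and generative parameters of a synthetic dataset."""

    module_of: dict  # gene -> module id (background genes absent)
    modules: dict  # module id -> list of member genes
    params: dict
    seed: int
    drivers: dict = field(default_factory=dict)  # cancer_type -> list of genes
    driver_module: dict = field(default_factory=dict)  # cancer_type -> module id
    effective_drugs: set = field(default_factory=set)
    drug_dags: dict = field(default_factory=dict)  # drug_id -> list of genes

    def to_json(self, path) -> None:
        payload = {
            "modules": self.modules,
            "params": self.params,
            "seed": self.seed,
            "drivers": self.drivers,
            "driver_module": self.driver_module,
            "effective_drugs": sorted(self.effective_drugs),
            "drug_dags": self.drug_dags,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def simulate_essentiality(
    n_genes: int = 2000,
    n_cells: int = 80,
    n_modules: int = 5,
    module_size: int = 40,
    beta: float = 1.0,
    sigma: float = 0.5,
    missing_rate: float = 0.0,
    n_lineages: int = 4,
    seed: int = 0,
) -> tuple[EssentialityMatrix, SyntheticTruth]:
    """Essentiality matrix with planted co-functional modules.

    The first ``n_modules * module_size`` genes are assigned to modules in
    blocks; cell lines get lineage labels round-robin. ``missing_rate``
    masks entries uniformly at random (exercises imputation).
    """
    if n_modules * module_size > n_genes:
        raise ValueError("modules do not fit into the gene count")
    if sigma <= 0:
        raise ValueError("noise sd must be positive")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes - 1))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]
    cells = [f"CL{i:04d}" for i in range(n_cells)]

    activity = rng.standard_normal((n_modules, n_cells))
    values = rng.normal(0.0, sigma, size=(n_genes, n_cells))
    modules: dict[int, list[str]] = {}
    module_of: dict[str, int] = {}
    for m in range(n_modules):
        lo, hi = m * module_size, (m + 1) * module_size
        values[lo:hi, :] += beta * activity[m]
        modules[m] = genes[lo:hi]
        for g in modules[m]:
            module_of[g] = m
    if missing_rate > 0:
        mask = rng.random((n_genes, n_cells)) < missing_rate
        # keep at least one observed value per gene and per cell line
        mask[:, 0] = False
        values = np.where(mask, np.nan, values)

    lineage = pd.Series(
        [f"cancer_{i % n_lineages}" for i in range(n_cells)], index=cells, name="lineage"
    )
    matrix = EssentialityMatrix(
        pd.DataFrame(values, index=genes, columns=cells), lineage=lineage
    )
    truth = SyntheticTruth(
        module_of=module_of,
        modules=modules,
        params={
            "n_genes": n_genes,
            "n_cells": n_cells,
            "n_modules": n_modules,
            "module_size": module_size,
            "beta": beta,
            "sigma": sigma,
            "missing_rate": missing_rate,
            "n_lineages": n_lineages,
        },
        seed=seed,
    )
    return matrix, truth


def simulate_drivers(
    truth: SyntheticTruth, cancer_type: str, n_drivers: int, seed: int = 0
) -> list[str]:
    """Plant driver genes for a cancer type inside one designated module.

    Each cancer type is bound to the next unused module (in id order); the
    drivers are a random subset of that module's genes.
    """
    if cancer_type in truth.driver_module:
        module_id = truth.driver_module[cancer_type]
    else:
        used = set(truth.driver_module.values())
        free = [m for m in sorted(truth.modules) if m not in used]
        if not free:
            raise ValueError("no unused module left for a new cancer type")
        module_id = free[0]
    members = truth.modules[module_id]
    if n_drivers > len(members):
        raise ValueError(
            f"cannot draw {n_drivers} drivers from a module of {len(members)} genes"
        )
    rng = np.random.default_rng(seed)
    drivers = sorted(rng.choice(members, size=n_drivers, replace=False).tolist())
    truth.driver_module[cancer_type] = module_id
    truth.drivers[cancer_type] = drivers
    return drivers


def simulate_drug_table(
    truth: SyntheticTruth,
    cancer_type: str,
    n_effective: int = 5,
    n_null: int = 45,
    dags_per_drug: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, set]:
    """Drug-gene association table with planted effective drugs.

    Effective drugs draw their DAGs from the cancer type's driver module;
    null drugs draw random genes from the whole gene universe. Association
    types alternate between ``direct_target`` and ``biomarker``.
    """
    if min(n_effective, n_null) < 0 or dags_per_drug < 1:
        raise ValueError("counts must be positive")
    if cancer_type not in truth.driver_module:
        raise ValueError(f"no drivers planted for {cancer_type!r}; run simulate_drivers")
    rng = np.random.default_rng(seed)
    module_genes = truth.modules[truth.driver_module[cancer_type]]
    n_genes_total = truth.params["n_genes"]
    width = len(str(n_genes_total - 1))
    universe = [f"G{i:0{width}d}" for i in range(n_genes_total)]

    rows = []
    effective = set()
    for d in range(n_effective + n_null):
        drug_id = f"DRUG{d:04d}"
        if d < n_effective:
            pool = module_genes
            effective.add(drug_id)
        else:
            pool = universe
        dags = sorted(
            rng.choice(pool, size=min(dags_per_drug, len(pool)), replace=False).tolist()
        )
        truth.drug_dags[drug_id] = dags
        for i, g in enumerate(dags):
            rows.append(
                {
                    "drug_id": drug_id,
                    "gene": g,
                    "association_type": "direct_target" if i % 2 == 0 else "biomarker",
                }
            )
    truth.effective_drugs |= effective
    return pd.DataFrame(rows), effective


def simulate_response(
    truth: SyntheticTruth,
    tc_true: pd.Series,
    alpha: float = 1.0,
    sigma_r: float = 0.5,
    n_cell_lines: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-drug, per-cell-line IC50 table with a planted TC dependence.

    The potency ``-log10(IC50)`` of drug d in each cell line is
    ``alpha * z(tc_true[d]) + N(0, sigma_r)`` where ``z`` standardises the
    true effect across drugs.
    """
    if alpha < 0 or sigma_r < 0:
        raise ValueError("alpha and sigma_r must be non-negative")
    rng = np.random.default_rng(seed)
    effect = tc_true.to_numpy(dtype=float)
    sd = effect.std()
    z = (effect - effect.mean()) / sd if sd > 0 else np.zeros_like(effect)
    rows = []
    for j, drug in enumerate(tc_true.index):
        potency = alpha * z[j] + rng.normal(0.0, sigma_r, size=n_cell_lines)
        for c in range(n_cell_lines):
            rows.append(
                {
                    "drug_id": drug,
                    "cell_line": f"CL{c:04d}",
                    "ic50": float(10.0 ** (-potency[c])),
                }
            )
    return pd.DataFrame(rows)


def simulate_expression_survival(
    truth: SyntheticTruth,
    cancer_type: str,
    n_patients: int = 200,
    gamma: float = 1.0,
    censor_rate: float = 0.2,
    baseline_rate: float = 1e-3,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient expression and survival tables tied to the driver module.

    Each patient has a latent module activity ~ N(0, 1); driver-module genes
    load on it (coefficient 1) plus noise, other genes are pure noise. Event
    times are exponential with rate ``baseline_rate * exp(gamma * activity)``
    (higher module activity -> worse outcome when gamma > 0) under
    independent exponential censoring tuned to ``censor_rate``.
    """
    if n_patients < 4:
        raise ValueError("need at least 4 patients")
    if cancer_type not in truth.driver_module:
        raise ValueError(f"no drivers planted for {cancer_type!r}")
    rng = np.random.default_rng(seed)
    module_genes = set(truth.modules[truth.driver_module[cancer_type]])
    n_genes_total = truth.params["n_genes"]
    width = len(str(n_genes_total - 1))
    genes = [f"G{i:0{width}d}" for i in range(n_genes_total)]
    patients = [f"P{i:04d}" for i in range(n_patients)]

    activity = rng.standard_normal(n_patients)
    expr = rng.normal(0.0, noise_sd, size=(n_patients, len(genes)))
    member = np.fromiter((g in module_genes for g in genes), bool, len(genes))
    expr[:, member] += activity[:, None]
    expr_df = pd.DataFrame(expr, index=patients, columns=genes)

    rate = baseline_rate * np.exp(gamma * activity)
    event_time = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        c_rate = baseline_rate * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / c_rate, size=n_patients)
    else:
        censor_time = np.full(n_patients, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    surv = pd.DataFrame(
        {"patient": patients, "time": np.maximum(time, 1e-6), "event": event}
    ).set_index("patient")
    return expr_df, surv
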