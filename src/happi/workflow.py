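"""Per-gene testing across a whole presence/absence matrix.

Genes are statistically independent under the model, so each gene gets its
own fit and test; permutation seeds are spawned per gene from a single
root seed so results do not depend on execution order or thread count.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import glm_lrt, glm_rao
from .data_io import GenePresenceDataset
from .em import (
    HappiConfig,
    PermutationConfig,
    TestSpec,
    bh_adjust,
    test_gene,
)

__all__ = ["run_gene_tests", "RunManifest", "METHODS"]

METHODS = ("happi-a", "happi-np", "glm-lrt", "glm-rao")


@dataclass
class RunManifest:
    """Reproducibility record for a whole-matrix run."""

    config: dict
    seed: int | None
    methods: list
    n_genes: int
    n_genomes: int
    wall_clock_s: float
    convergence: dict
    version: str = ""
    input_hashes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "methods": list(self.methods),
            "config": self.config,
            "n_genes": self.n_genes,
            "n_genomes": self.n_genomes,
            "wall_clock_s": self.wall_clock_s,
            "convergence": self.convergence,
            "input_hashes": self.input_hashes,
        }


def _gene_rows(gene_id, y, X, M, spec, config, methods, perm_B, gene_seed):
    rows = []
    skip = None
    tested_cols = spec.tested or ()
    for k in tested_cols:
        if np.ptp(X[:, k]) == 0:
            skip = f"tested covariate column {k} is constant"
    if skip is not None:
        for m in methods:
            rows.append({"gene_id": gene_id, "method": m, "statistic": np.nan,
                         "p_value": np.nan, "converged_alt": False,
                         "converged_null": False, "n_iter_alt": 0,
                         "n_iter_null": 0, "skip_reason": skip})
        return rows
    for m in methods:
        if m == "happi-a":
            res = test_gene(y, X, M, config, spec, method="asymptotic")
        elif m == "happi-np":
            perm = PermutationConfig(B=perm_B, seed=gene_seed)
            res = test_gene(y, X, M, config, spec, method="permutation",
                            perm=perm)
        elif m == "glm-lrt":
            res = glm_lrt(y, X, spec)
        elif m == "glm-rao":
            res = glm_rao(y, X, spec)
        else:
            raise ValueError(f"unknown method {m!r}")
        alt, null = res.fit_alt, res.fit_null
        rows.append({
            "gene_id": gene_id, "method": m, "statistic": res.Q_lrt,
            "p_value": res.p_value,
            "converged_alt": bool(alt.converged) if alt else
            bool(getattr(res, "converged", True)),
            "converged_null": bool(null.converged) if null else
            bool(getattr(res, "converged", True)),
            "n_iter_alt": alt.n_iter if alt else 0,
            "n_iter_null": null.n_iter if null else 0,
            "skip_reason": "",
        })
    return rows


def run_gene_tests(dataset: GenePresenceDataset,
                   test_covariates,
                   methods=("happi-a",),
                   config: HappiConfig | None = None,
                   perm_B: int = 1000,
                   seed: int = 0,
                   n_jobs: int = 1,
                   fdr_alpha: float | None = None) -> tuple[pd.DataFrame,
                                                            RunManifest]:
    """Test every gene in the dataset against the chosen covariates.

    ``test_covariates`` are column indices of ``dataset.X`` (or covariate
    names) tested jointly against zero.  Benjamini-Hochberg q-values are
    computed within each method across genes with a valid p-value; if
    ``fdr_alpha`` is given, a boolean ``significant`` column thresholds the
    q-values.  Genes are independent, so ``n_jobs > 1`` parallelises across
    genes; per-gene seeds are spawned from ``seed`` up front, so the worker
    count never changes the results.
    """
    config = config or HappiConfig()
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    idx = []
    for c in np.atleast_1d(test_covariates):
        if isinstance(c, str):
            if c not in dataset.covariate_names:
                raise KeyError(f"covariate {c!r} not found")
            idx.append(dataset.covariate_names.index(c))
        else:
            idx.append(int(c))
    spec = TestSpec.coefficients(idx, p=dataset.X.shape[1])

    root = np.random.SeedSequence(seed)
    t0 = time.perf_counter()
    gene_seeds = [
        int(np.random.default_rng(
            np.random.SeedSequence(entropy=root.entropy, spawn_key=(g,))
        ).integers(2**31))
        for g in range(dataset.n_genes)
    ]
    args = [(gene_id, dataset.Y[g].astype(float), dataset.X, dataset.M,
             spec, config, list(methods), perm_B, gene_seeds[g])
            for g, gene_id in enumerate(dataset.gene_ids)]
    if n_jobs == 1:
        per_gene = [_gene_rows(*a) for a in args]
    else:
        from joblib import Parallel, delayed

        per_gene = Parallel(n_jobs=n_jobs)(delayed(_gene_rows)(*a)
                                           for a in args)
    rows = [row for gene in per_gene for row in gene]
    table = pd.DataFrame(rows)
    table["q_value"] = np.nan
    for m in methods:
        mask = (table["method"] == m) & table["p_value"].notna()
        if mask.any():
            table.loc[mask, "q_value"] = bh_adjust(table.loc[mask, "p_value"])
    if fdr_alpha is not None:
        table["significant"] = table["q_value"] < fdr_alpha
    wall = time.perf_counter() - t0

    conv = {
        m: int(((table["method"] == m) & table["converged_alt"]
                & table["converged_null"]).sum())
        for m in methods
    }
    from . import __version__

    manifest = RunManifest(
        config={k: (v if np.isscalar(v) or v is None else str(v))
                for k, v in config.__dict__.items()},
        seed=seed, methods=list(methods), n_genes=dataset.n_genes,
        n_genomes=dataset.n_genomes, wall_clock_s=wall, convergence=conv,
        version=__version__,
    )
    return table, manifest
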