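"""Whole-matrix workflow: files in, BH-adjusted result table out.

Writes a small presence/absence matrix and metadata table to a temporary
directory, runs per-gene quality-adjusted tests plus the GLM baselines,
and prints the result table.  The same workflow is exposed on the shell as

    happi test --matrix matrix.tsv --metadata meta.tsv \
        --genome-id-col genome --covariates site --quality-cols coverage \
        --method asymptotic --baselines --out results.tsv
"""

import tempfile
from pathlib import Path

import numpy as np

from happi import HappiConfig, load_dataset, run_gene_tests, write_results

rng = np.random.default_rng(3)
n = 24
genomes = [f"mag{i:02d}" for i in range(n)]
site = rng.permutation(["tongue"] * 12 + ["plaque"] * 12)
coverage = np.round(rng.uniform(1.0, 26.0, n), 2)

tmp = Path(tempfile.mkdtemp())
genes = {"cog_core": np.ones(n, int),
         "cog_site": (site == "tongue").astype(int),
         "cog_rand": rng.integers(0, 2, n)}
# imperfect detection: drop some observations in low-coverage genomes
for name in ("cog_core", "cog_site"):
    miss = (coverage < 8) & (rng.uniform(size=n) < 0.5)
    genes[name] = np.where(miss, 0, genes[name])

lines = ["gene_id\t" + "\t".join(genomes)]
for g, row in genes.items():
    lines.append(g + "\t" + "\t".join(map(str, row)))
(tmp / "matrix.tsv").write_text("\n".join(lines) + "\n")
meta = ["genome\tsite\tcoverage"] + [
    f"{g}\t{s}\t{c}" for g, s, c in zip(genomes, site, coverage)
]
(tmp / "meta.tsv").write_text("\n".join(meta) + "\n")

dataset = load_dataset(tmp / "matrix.tsv", tmp / "meta.tsv", "genome",
                       ["site"], ["coverage"])
config = HappiConfig(epsilon=0.0, t_max=1000, delta=0.1)
table, manifest = run_gene_tests(dataset, ["site[tongue]"],
                                 methods=("happi-a", "glm-lrt", "glm-rao"),
                                 config=config, seed=0)
write_results(table, tmp / "results.tsv")
cols = ["gene_id", "method", "statistic", "p_value", "q_value"]
print(table[cols].to_string(index=False))
print()
print(f"results written to {tmp/'results.tsv'};",
      f"{manifest.n_genes} genes x {len(manifest.methods)} methods,")
print("q_value = Benjamini-Hochberg adjusted p within each method.")
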