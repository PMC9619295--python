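"""Synthetic two-condition expression data with known ground truth.

The generator plants three gene classes on a Gaussian latent scale:

* **null** genes — i.i.d. noise, independent of the condition;
* **de** genes — a conditional mean shift (in s.d. units) in treatment,
  detectable by the MV screen;
* **rewired** module genes — an equicorrelated block whose pairwise
  correlation differs between treatment and control (planted rewiring for
  the differential co-expression network), combined with the same mean
  shift as the DE class so the module survives the screening step, as
  phenotype-driven genes in real data are typically both differentially
  expressed and rewired.

Latent values are exponentiated by default so the emitted matrix is
positive and right-skewed like processed RNA-seq abundances; rank-based
statistics are unaffected by this monotone transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONTROL, TREATMENT, ExpressionMatrix


@dataclass(frozen=True)
class SyntheticDesign:
    """Ground-truth design of a synthetic dataset.

    Sizes are per stage; ``n_stages > 1`` repeats the design over
    consecutive three-week windows with independent noise.
    """

    n_null: int = 60
    n_de: int = 15
    n_module: int = 10
    n_treat: int = 12
    n_ctrl: int = 12
    de_shift: float = 2.0
    module_shift: float | None = None  # None -> de_shift
    module_corr_treat: float = 0.9
    module_corr_ctrl: float = 0.1
    noise_sd: float = 1.0
    lognormal: bool = True
    n_stages: int = 1
    weeks_per_stage: int = 3
    first_week: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.n_null, self.n_de, self.n_module) < 0 or self.n_genes < 2:
            raise ValueError("gene counts must be non-negative and total >= 2")
        if self.n_treat < 2 or self.n_ctrl < 2:
            raise ValueError("need at least 2 samples per condition")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for r in (self.module_corr_treat, self.module_corr_ctrl):
            if not -1 < r < 1:
                raise ValueError("module correlations must be in (-1, 1)")
            if self.n_module > 1 and r < -1.0 / (self.n_module - 1):
                raise ValueError(
                    f"equicorrelation {r} infeasible for a module of {self.n_module} genes"
                )

    @property
    def n_genes(self) -> int:
        return self.n_null + self.n_de + self.n_module

    @property
    def effective_module_shift(self) -> float:
        return self.de_shift if self.module_shift is None else self.module_shift


def _equicorrelated(rng, n_genes: int, n_samples: int, corr: float, sd: float) -> np.ndarray:
    """Genes x samples block with pairwise correlation ``corr``."""
    if n_genes == 0:
        return np.empty((0, n_samples))
    if corr >= 0:
        f = rng.standard_normal(n_samples)
        e = rng.standard_normal((n_genes, n_samples))
        z = np.sqrt(corr) * f[None, :] + np.sqrt(1.0 - corr) * e
    else:
        cov = np.full((n_genes, n_genes), corr)
        np.fill_diagonal(cov, 1.0)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("infeasible module correlation structure") from exc
        z = chol @ rng.standard_normal((n_genes, n_samples))
    return sd * z


def generate(design: SyntheticDesign = SyntheticDesign()):
    """Generate (ExpressionMatrix, metadata DataFrame, truth DataFrame).

    Fixed seed gives bit-identical output.  The truth table has columns
    gene_id, class ({null, de, rewired}), de_shift, module_id.
    """
    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    d = design
    gene_ids = (
        [f"null_{i:04d}" for i in range(d.n_null)]
        + [f"de_{i:04d}" for i in range(d.n_de)]
        + [f"mod_{i:04d}" for i in range(d.n_module)]
    )
    classes = ["null"] * d.n_null + ["de"] * d.n_de + ["rewired"] * d.n_module
    shifts = [0.0] * d.n_null + [d.de_shift] * d.n_de + [d.effective_module_shift] * d.n_module

    blocks, sample_ids, meta_rows = [], [], []
    for stage in range(1, d.n_stages + 1):
        cols = {}
        for cond, n_cond, corr in (
            (TREATMENT, d.n_treat, d.module_corr_treat),
            (CONTROL, d.n_ctrl, d.module_corr_ctrl),
        ):
            z = np.empty((d.n_genes, n_cond))
            z[: d.n_null] = d.noise_sd * rng.standard_normal((d.n_null, n_cond))
            z[d.n_null : d.n_null + d.n_de] = d.noise_sd * rng.standard_normal((d.n_de, n_cond))
            z[d.n_null + d.n_de :] = _equicorrelated(rng, d.n_module, n_cond, corr, d.noise_sd)
            if cond == TREATMENT:
                z[d.n_null : d.n_null + d.n_de] += d.de_shift * d.noise_sd
                z[d.n_null + d.n_de :] += d.effective_module_shift * d.noise_sd
            cols[cond] = z
            weeks = [
                d.first_week + (stage - 1) * d.weeks_per_stage + (j % d.weeks_per_stage)
                for j in range(n_cond)
            ]
            for j in range(n_cond):
                sid = f"s{stage}_{cond[:1]}{j + 1:02d}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "condition": cond, "week": weeks[j],
                     "replicate": j // d.weeks_per_stage + 1}
                )
        blocks.append(np.hstack([cols[TREATMENT], cols[CONTROL]]))
    values = np.hstack(blocks)
    if d.lognormal:
        values = np.exp(values)
    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "class": classes,
        "de_shift": shifts,
        "module_id": [1 if c == "rewired" else 0 for c in classes],
    })
    return expr, meta, truth


def tiny_fixture():
    """Deterministic 6-gene x 8-sample dataset with hand-checkable values.

    Four treatment and four control samples in weeks 3-5.  Gene ``g1``
    separates the conditions perfectly; ``g2`` is constant; the rest are
    small fixed patterns convenient for enumerating CDFs and gray
    correlations by hand.
    """
    values = np.array([
        [5.0, 6.0, 7.0, 8.0, 1.0, 2.0, 3.0, 4.0],   # g1: perfect separation
        [3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0],   # g2: constant
        [1.0, 4.0, 2.0, 6.0, 3.0, 5.0, 8.0, 7.0],   # g3: interleaved
        [2.0, 2.0, 5.0, 5.0, 2.0, 2.0, 5.0, 5.0],   # g4: ties
        [8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0],   # g5: reversed g1
        [1.0, 2.0, 1.0, 2.0, 9.0, 9.0, 1.0, 2.0],   # g6: asymmetric
    ])
    gene_ids = [f"g{i}" for i in range(1, 7)]
    sample_ids = [f"t{i}" for i in range(1, 5)] + [f"c{i}" for i in range(1, 5)]
    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "condition": [TREATMENT] * 4 + [CONTROL] * 4,
        "week": [3, 3, 4, 5, 3, 4, 4, 5],
        "replicate": [1, 2, 1, 1, 1, 1, 2, 1],
    })
    return expr, meta
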