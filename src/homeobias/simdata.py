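"""Synthetic homoeolog-pair expression datasets with known ground truth.

The generator emulates the study design the pipeline targets: three
biological replicates of FPKM-scale expression for two diploid parents
and the allopolyploid (homoeolog-resolved), over a map of orthologous
homoeolog pairs.  Each pair is drawn from a *template* — a quadruple of
true means (A_r, C_o, A_n, C_n) on a unit scale — whose truth labels are
computed by the exact-mean classifier (:func:`homeobias.pairclass.truth_label`),
then scaled by a per-pair base mean and perturbed with multiplicative
lognormal replicate noise: ``value = mean * exp(N(0, sigma^2))`` with
``sigma = sqrt(log(1 + cv^2))``, so the replicate coefficient of
variation equals ``cv`` and values stay non-negative.

Defaults reflect the study conditions: 3 replicates, a 4-fold template
effect size, cv = 0.2 replicate noise, base means log-uniform on
[2, 500] FPKM, and a template mixture mirroring the category composition
observed in a resynthesized allotetraploid leaf transcriptome (~46% no
change, ~39% ELD biased toward the A genome and the higher parent, ~5%
additivity, ~9% transgressive, nearly all upward).

A Poisson per-base depth simulator provides matching whole-genome
coverage tracks for the chromosome-integrity module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pairclass
from .errors import InvalidParameterError
from .io import ExpressionTable, write_expression, write_pair_map

DEFAULT_FOLD_CHANGE = 4.0
DEFAULT_CV = 0.2
DEFAULT_N_REPLICATES = 3
DEFAULT_BASE_MEAN_RANGE = (2.0, 500.0)

#: scale used by the below-cutoff template (mean FPKM < 1 in every species)
_LOW_EXPRESSION_SCALE = 0.4


@dataclass(frozen=True)
class SimTemplate:
    """Unit-scale true means for one expression state plus cached truth.

    ``scale`` fixes the absolute base mean (used by the below-cutoff
    template); when None the base mean is drawn per pair.
    """

    name: str
    mu_Ar: float
    mu_Co: float
    mu_An: float
    mu_Cn: float
    scale: float | None = None

    def __post_init__(self):
        for v in (self.mu_Ar, self.mu_Co, self.mu_An, self.mu_Cn):
            if v < 0:
                raise InvalidParameterError(f"template {self.name}: means must be >= 0")

    @property
    def means(self) -> tuple[float, float, float, float]:
        return (self.mu_Ar, self.mu_Co, self.mu_An, self.mu_Cn)

    @property
    def truth(self) -> pairclass.TruthLabels:
        """Truth labels, always recomputed from the exact-mean classifier."""
        return pairclass.truth_label(*self.means)


def default_templates(fold_change: float = DEFAULT_FOLD_CHANGE) -> list[SimTemplate]:
    """The built-in template set at effect size ``fold_change`` (> 1).

    Covers no change, every ELD category with the explanation mechanisms
    (dominant copy down, nondominant up — jointly with dominant down,
    since an exact pair total pinned to one parent cannot rise by the
    nondominant copy alone — nondominant down, both down), both
    additivity orientations, all six transgressive subclasses, the four
    bias transitions, and a below-cutoff template exercising the
    expression filter.
    """
    if fold_change <= 1:
        raise InvalidParameterError(f"fold_change must be > 1, got {fold_change}")
    f = float(fold_change)
    half_hi = (f + 1) / 2.0
    half_lo = (f - 1) / 2.0
    T = SimTemplate
    return [
        T("no_change", 1, 1, 0.5, 0.5),
        # ELD-A (pair total matches parent A)
        T("eld_A_higher_domdown", f, 1, f - 1, 1),
        T("eld_A_higher_nondomup", f, 1, half_lo, half_hi),
        T("eld_A_lower_nondomdown", 1, f, 1, 0),
        T("eld_A_lower_bothdown", 1, f, 0.5, 0.5),
        # ELD-C (pair total matches parent C)
        T("eld_C_higher_domdown", 1, f, 1, f - 1),
        T("eld_C_higher_nondomup", 1, f, half_hi, half_lo),
        T("eld_C_lower_nondomdown", f, 1, 0, 1),
        T("eld_C_lower_bothdown", f, 1, 0.5, 0.5),
        # additivity (pair total strictly between the parents)
        T("additivity_I", 1, f, 1, half_lo),
        T("additivity_XII", f, 1, half_lo, 1),
        # transgressive up, split by the parental relation
        T("trans_up_V", 1, f, f, f),
        T("trans_up_VI", 1, 1, 1, 1),
        T("trans_up_VIII", f, 1, f, f),
        # transgressive down
        T("trans_down_III", 1, f, 0.25, 0.25),
        T("trans_down_VII", 1, 1, 0.25, 0.25),
        T("trans_down_X", f, 1, 0.25, 0.25),
        # bias-transition exemplars (ELD truth follows from the means)
        T("bias_maintained", f, 1, f / 2, 0.5),
        T("bias_novel", 1, 1, f, 1),
        T("bias_reverted", f, 1, 1, 1),
        T("bias_switched", f, 1, 1, f),
        # below the FPKM cutoff in every species
        T("low_expression", 1, 1, 0.5, 0.5, scale=_LOW_EXPRESSION_SCALE),
    ]


#: default template mixture mirroring the observed category composition
DEFAULT_TEMPLATE_MIX = {
    "no_change": 0.42,
    "eld_A_higher_domdown": 0.12,
    "eld_A_higher_nondomup": 0.06,
    "eld_A_lower_nondomdown": 0.03,
    "eld_A_lower_bothdown": 0.03,
    "eld_C_higher_domdown": 0.07,
    "eld_C_higher_nondomup": 0.04,
    "eld_C_lower_nondomdown": 0.02,
    "eld_C_lower_bothdown": 0.02,
    "additivity_I": 0.025,
    "additivity_XII": 0.025,
    "trans_up_V": 0.03,
    "trans_up_VI": 0.02,
    "trans_up_VIII": 0.03,
    "trans_down_III": 0.001,
    "trans_down_VII": 0.001,
    "trans_down_X": 0.001,
    "bias_maintained": 0.01,
    "bias_novel": 0.01,
    "bias_reverted": 0.01,
    "bias_switched": 0.007,
    "low_expression": 0.02,
}


@dataclass
class SimConfig:
    """Parameters of one simulated dataset."""

    n_pairs: int
    template_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATE_MIX)
    )
    base_mean_range: tuple[float, float] = DEFAULT_BASE_MEAN_RANGE
    fold_change: float = DEFAULT_FOLD_CHANGE
    cv: float = DEFAULT_CV
    n_replicates: int = DEFAULT_N_REPLICATES
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 1:
            raise InvalidParameterError("n_pairs must be >= 1")
        if not self.template_mix:
            raise InvalidParameterError("template_mix must not be empty")
        total = sum(self.template_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(f"template_mix proportions sum to {total}, not 1")
        if any(w < 0 for w in self.template_mix.values()):
            raise InvalidParameterError("template_mix proportions must be >= 0")
        lo, hi = self.base_mean_range
        if not (0 < lo <= hi):
            raise InvalidParameterError("base_mean_range must satisfy 0 < lo <= hi")
        if self.fold_change <= 1:
            raise InvalidParameterError("fold_change must be > 1")
        if self.cv < 0:
            raise InvalidParameterError("cv must be >= 0")
        if self.n_replicates < 2:
            raise InvalidParameterError("n_replicates must be >= 2")


@dataclass
class SimulatedDataset:
    """In-memory result of :func:`simulate_dataset`."""

    parent_a: ExpressionTable
    parent_c: ExpressionTable
    polyploid: ExpressionTable
    pair_map: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "parent_a": outdir / "parentA.tsv",
            "parent_c": outdir / "parentC.tsv",
            "polyploid": outdir / "polyploid.tsv",
            "pairs": outdir / "pairs.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_expression(self.parent_a, paths["parent_a"])
        write_expression(self.parent_c, paths["parent_c"])
        write_expression(self.polyploid, paths["polyploid"])
        write_pair_map(self.pair_map, paths["pairs"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.12g")
        return {k: str(v) for k, v in paths.items()}


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Draw a full three-species dataset with per-pair ground truth.

    Deterministic given ``config.seed`` (bit-identical tables on rerun).
    """
    templates = {t.name: t for t in default_templates(config.fold_change)}
    unknown = set(config.template_mix) - set(templates)
    if unknown:
        raise InvalidParameterError(f"unknown template names in mix: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    names = list(config.template_mix)
    probs = np.array([config.template_mix[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    n = config.n_pairs
    choice = rng.choice(len(names), size=n, p=probs)

    lo, hi = config.base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    unit_means = np.empty((n, 4), dtype=float)
    template_names = np.empty(n, dtype=object)
    for i, c in enumerate(choice):
        t = templates[names[c]]
        template_names[i] = t.name
        unit_means[i] = t.means
        if t.scale is not None:
            base[i] = t.scale
    true_means = unit_means * base[:, None]

    sigma = float(np.sqrt(np.log1p(config.cv**2)))
    r = config.n_replicates
    if sigma == 0.0:
        noise = np.ones((n, 4, r))
    else:
        noise = np.exp(rng.normal(0.0, sigma, size=(n, 4, r)))
    values = true_means[:, :, None] * noise  # (pairs, species-slot, replicate)

    gene_a = np.array([f"BraA{i + 1:05d}" for i in range(n)])
    gene_c = np.array([f"BolC{i + 1:05d}" for i in range(n)])
    pair_id = np.array([f"pair{i + 1:05d}" for i in range(n)])

    cols_a = [f"AA_R{j + 1}" for j in range(r)]
    cols_c = [f"CC_R{j + 1}" for j in range(r)]
    cols_p = [f"AACC_R{j + 1}" for j in range(r)]
    parent_a = ExpressionTable(
        pd.DataFrame(values[:, 0, :], index=pd.Index(gene_a, name="gene_id"), columns=cols_a),
        "parentA",
    )
    parent_c = ExpressionTable(
        pd.DataFrame(values[:, 1, :], index=pd.Index(gene_c, name="gene_id"), columns=cols_c),
        "parentC",
    )
    poly_index = pd.Index(np.concatenate([gene_a, gene_c]), name="gene_id")
    poly_data = pd.DataFrame(
        np.vstack([values[:, 2, :], values[:, 3, :]]), index=poly_index, columns=cols_p
    )
    subgenome = pd.Series(["A"] * n + ["C"] * n, index=poly_index, name="subgenome")
    polyploid = ExpressionTable(poly_data, "polyploid", subgenome)

    pair_map = pd.DataFrame(
        {"pair_id": pair_id, "gene_id_A": gene_a, "gene_id_C": gene_c}
    )
    truth_rows = []
    truth_cache = {name: templates[name].truth for name in set(template_names)}
    for i in range(n):
        lab = truth_cache[template_names[i]]
        truth_rows.append(
            (
                pair_id[i],
                template_names[i],
                base[i],
                lab.category,
                lab.group,
                lab.eld_direction,
                lab.parent_state,
                lab.progeny_state,
                lab.transition,
                lab.change_A,
                lab.change_C,
                lab.mechanism,
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "pair_id",
            "template",
            "base_mean",
            "truth_category",
            "truth_group",
            "truth_eld_direction",
            "truth_bias_parent",
            "truth_bias_progeny",
            "truth_transition",
            "truth_change_A",
            "truth_change_C",
            "truth_mechanism",
        ],
    )
    return SimulatedDataset(parent_a, parent_c, polyploid, pair_map, truth, config)


def simulate_depth(
    chrom_lengths: dict[str, int],
    mean_depth: dict[str, float] | float,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-base Poisson depth track (samtools-depth layout, 1-based).

    ``mean_depth`` may be a scalar or a per-chromosome mapping; a mean of
    0 emits an all-zero chromosome (simulating a missing chromosome).
    """
    if not chrom_lengths:
        raise InvalidParameterError("chrom_lengths must not be empty")
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise InvalidParameterError(f"{chrom}: length must be > 0")
        mu = mean_depth[chrom] if isinstance(mean_depth, dict) else mean_depth
        if mu < 0:
            raise InvalidParameterError(f"{chrom}: mean depth must be >= 0")
        depth = (
            np.zeros(length, dtype=np.int64)
            if mu == 0
            else rng.poisson(mu, size=length)
        )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.arange(1, length + 1, dtype=np.int64),
                    "depth": depth,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
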