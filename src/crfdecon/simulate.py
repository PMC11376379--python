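"""Synthetic data with planted ground truth.

The generator emulates the structure of an ethanol-inducible TPS experiment:
two genotypes (iTPS carrying the inducible TPS construct, alcR the
empty-vector control) sprayed with ethanol or water and profiled in
replicated bulk RNA-seq, plus a reference panel of sugar-manipulation
contrasts, a hierarchical functional-category mapping and an external
(SnRK1-like) response signature.

Planted gene classes:

* direct     -- responds to induction with the same sign as its (nonzero)
                sugar-panel CRF; should be recovered as G1;
* indirect   -- responds with the opposite sign to its CRF; recovered as G2;
* orthogonal -- responds to induction but has |CRF| near zero; recovered
                as G0;
* offtarget  -- an ethanol/alcR artifact: the same strong shift is planted
                in BOTH the iTPS and alcR ethanol cells; should be flagged
                as a same-direction shared DEG and excluded;
* null       -- no response to anything.

Replicate counts are beta-binomially overdispersed around per-sample gene
proportions; an optional log-normal noise mode breaks the test's
distributional assumption on purpose (robustness checks).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import BINMap, CountMatrix

__all__ = [
    "CLASSES",
    "DEFAULT_FRACTIONS",
    "PANEL_LABELS",
    "TruthTable",
    "SyntheticDataset",
    "generate_truth",
    "generate_counts",
    "generate_panel",
    "generate_external",
    "generate_lengths",
    "simulate_null_groups",
    "generate_binmap",
    "simulate_all",
]

CLASSES = ("direct", "indirect", "orthogonal", "offtarget", "null")

#: default class proportions: 40/30/30 direct/indirect/orthogonal among the
#: sugar-informative responsive genes, a small off-target component, rest null
DEFAULT_FRACTIONS = (0.20, 0.15, 0.15, 0.01, 0.49)

#: nine reference sugar-manipulation contrasts (sugar feeding of starved
#: seedlings, starchless-mutant diel comparisons, low-CO2 illumination)
PANEL_LABELS = (
    "glc_addition",
    "suc_addition",
    "pgm_vs_wt_ZT4",
    "pgm_vs_wt_ZT8",
    "pgm_vs_wt_ZT12",
    "pgm_vs_wt_ZT16",
    "low_co2_4h",
    "glc_starved_seedlings",
    "suc_starved_seedlings",
)

#: top-level synthetic functional categories; each planted class is enriched
#: in its designated category
BIN_NAMES = {
    "1": "photosynthesis-like",
    "2": "specialized-metabolism-like",
    "3": "housekeeping-like",
    "4": "stress-like",
}
_DESIGNATED_BIN = {
    "direct": "1",
    "indirect": "2",
    "orthogonal": "3",
    "offtarget": "4",
    "null": None,
}


@dataclasses.dataclass
class TruthTable:
    """Planted per-gene ground truth.

    ``table`` columns: gene_class, true_itps_log2fc, true_crf,
    context_dependent, bins (semicolon-joined codes), true_external_log2fc
    (NaN until an external vector is generated).  ``panel`` is the
    noise-free K-contrast response panel.
    """

    table: pd.DataFrame
    panel: pd.DataFrame
    effect_scale: float

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def genes_of(self, gene_class: str) -> pd.Index:
        return self.table.index[self.table["gene_class"] == gene_class]


def _class_counts(n_genes: int, fractions) -> np.ndarray:
    """Floor-then-largest-remainder apportionment of genes to classes."""
    frac = np.asarray(fractions, dtype=float)
    if frac.shape != (len(CLASSES),):
        raise ValueError(f"fractions must have {len(CLASSES)} entries (order {CLASSES})")
    if (frac < 0).any() or abs(frac.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    exact = frac * n_genes
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = n_genes - counts.sum()
    # distribute the shortfall to the largest remainders (ties: class order)
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        counts[idx] += 1
    return counts


def generate_truth(
    n_genes: int,
    fractions=DEFAULT_FRACTIONS,
    effect_scale: float = 1.0,
    seed: int = 0,
    k_contrasts: int = 9,
    crf_scale: float = 0.5,
    orthogonal_crf_max: float = 0.05,
    context_fraction: float = 0.1,
) -> TruthTable:
    """Plant per-gene classes, effects, CRFs, panel rows and BIN codes.

    Effect magnitudes for responsive classes are effect_scale x U(1, 2)
    with random sign; off-target shifts are effect_scale x U(2, 3) so they
    are unambiguously detectable in both genotypes.  Sugar-responsive
    classes carry |CRF| near ``crf_scale``; orthogonal genes stay within
    ``orthogonal_crf_max``.  A ``context_fraction`` of the sugar-responsive
    genes get mixed-sign panel rows (zero-sum +-1.5 x effect_scale pattern)
    that leave the row mean - hence the CRF - unchanged.
    """
    if effect_scale <= 0:
        raise ValueError("effect_scale must be positive")
    if k_contrasts < 1:
        raise ValueError("k_contrasts must be >= 1")
    rng = np.random.default_rng(seed)
    counts = _class_counts(n_genes, fractions)
    gene_class = np.repeat(CLASSES, counts)
    gene_ids = pd.Index([f"ATSYN{i + 1:05d}" for i in range(n_genes)], name="gene_id")

    fc = np.zeros(n_genes)
    crf = np.zeros(n_genes)
    sign = rng.choice([-1.0, 1.0], size=n_genes)
    for cls in ("direct", "indirect", "orthogonal"):
        idx = np.flatnonzero(gene_class == cls)
        fc[idx] = sign[idx] * effect_scale * rng.uniform(1.0, 2.0, size=idx.size)
    idx = np.flatnonzero(gene_class == "offtarget")
    fc[idx] = sign[idx] * effect_scale * rng.uniform(2.0, 3.0, size=idx.size)

    idx = np.flatnonzero(gene_class == "direct")
    crf[idx] = np.sign(fc[idx]) * crf_scale * rng.uniform(0.9, 1.1, size=idx.size)
    idx = np.flatnonzero(gene_class == "indirect")
    crf[idx] = -np.sign(fc[idx]) * crf_scale * rng.uniform(0.9, 1.1, size=idx.size)
    idx = np.flatnonzero(gene_class == "orthogonal")
    crf[idx] = rng.uniform(-orthogonal_crf_max, orthogonal_crf_max, size=idx.size)

    # noise-free panel: constant rows at the CRF; context-dependent genes get
    # a zero-sum opposing-sign pattern on top (row mean unchanged)
    labels = list(PANEL_LABELS[:k_contrasts])
    labels += [f"extra_contrast_{i}" for i in range(len(labels) + 1, k_contrasts + 1)]
    panel = np.tile(crf[:, None], (1, k_contrasts)).astype(float)
    context = np.zeros(n_genes, dtype=bool)
    sugar_responsive = np.flatnonzero(np.isin(gene_class, ("direct", "indirect")))
    n_ctx = int(round(context_fraction * sugar_responsive.size))
    if n_ctx and k_contrasts >= 2:
        ctx_idx = rng.choice(sugar_responsive, size=n_ctx, replace=False)
        context[ctx_idx] = True
        half = k_contrasts // 2
        pattern = np.zeros(k_contrasts)
        pattern[:half] = 1.5 * effect_scale
        pattern[half : 2 * half] = -1.5 * effect_scale
        for g in ctx_idx:
            panel[g] += rng.permutation(pattern)

    bins = _assign_bins(gene_class, rng)

    table = pd.DataFrame(
        {
            "gene_class": gene_class,
            "true_itps_log2fc": fc,
            "true_crf": crf,
            "context_dependent": context,
            "bins": bins,
            "true_external_log2fc": np.nan,
        },
        index=gene_ids,
    )
    panel_df = pd.DataFrame(panel, index=gene_ids, columns=labels)
    return TruthTable(table=table, panel=panel_df, effect_scale=effect_scale)


def _assign_bins(gene_class: np.ndarray, rng) -> list[str]:
    """1-2 leaf BIN codes per gene; each class enriched in its designated BIN."""
    tops = list(BIN_NAMES)
    out = []
    for cls in gene_class:
        designated = _DESIGNATED_BIN[cls]
        if designated is not None and rng.random() < 0.6:
            top = designated
        else:
            top = tops[rng.integers(len(tops))]
        codes = [f"{top}.{rng.integers(1, 4)}"]
        if rng.random() < 0.1:
            other = tops[rng.integers(len(tops))]
            second = f"{other}.{rng.integers(1, 4)}"
            if second not in codes:
                codes.append(second)
        out.append(";".join(codes))
    return out


def generate_binmap(truth: TruthTable) -> BINMap:
    """Materialize the truth table's BIN codes as a MapMan-style mapping."""
    rows = []
    for gene, codes in truth.table["bins"].items():
        for code in codes.split(";"):
            rows.append((code, gene))
    assignments = pd.DataFrame(rows, columns=["bincode", "gene_id"])
    names = dict(BIN_NAMES)
    for code in sorted(set(assignments["bincode"])):
        top = code.split(".")[0]
        names.setdefault(code, f"{BIN_NAMES.get(top, 'category')} subprocess {code}")
    return BINMap(assignments=assignments, names=names)


def default_design(timepoints=("4h",), n_replicates: int = 4) -> pd.DataFrame:
    """Full factorial iTPS/alcR x ethanol/water x timepoint x replicate sheet."""
    rows = []
    for genotype in ("iTPS", "alcR"):
        for treatment in ("ethanol", "water"):
            for tp in timepoints:
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{genotype}_{treatment}_{tp}_r{rep}",
                            "genotype": genotype,
                            "treatment": treatment,
                            "timepoint": tp,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_counts(
    truth: TruthTable,
    design: pd.DataFrame | None = None,
    depth: float = 2e7,
    theta: float = 2.5e-7,
    seed: int = 0,
    baseline_log2_sd: float = 2.0,
    mapped_fraction: float = 0.1,
    noise_model: str = "betabinomial",
) -> CountMatrix:
    """Draw replicated counts for the factorial induction design.

    Baseline abundances are log-normal; the planted iTPS response shifts
    gene abundance in the (iTPS, ethanol) cells, off-target genes shift in
    BOTH ethanol cells.  Per replicate, the gene proportion is drawn from a
    Beta with variance p(1-p) x theta around the cell proportion (matching
    the DE test's model; ``noise_model="lognormal"`` misspecifies it on
    purpose) and counts are binomial against a library size varying +-20%
    around ``depth``.

    The simulated genes take ``mapped_fraction`` of the library at
    baseline: library sizes count all mapped reads, of which the matrix
    rows are a subset, so cross-gene competition from the planted shifts is
    buffered by the unmodelled majority of the transcriptome (proportions
    use the fixed baseline total as denominator).
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if noise_model not in ("betabinomial", "lognormal"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    if design is None:
        design = default_design()
    rng = np.random.default_rng(seed)
    genes = truth.gene_ids
    n_genes = len(genes)

    base = np.exp2(rng.normal(0.0, baseline_log2_sd, size=n_genes))
    fc = truth.table["true_itps_log2fc"].to_numpy()
    offtarget = (truth.table["gene_class"] == "offtarget").to_numpy()
    # the off-target class models the handful of *observed* alcR-binding
    # artifacts, so it is planted among well-measured genes (upper half of
    # the abundance distribution)
    base[offtarget] = np.exp2(
        np.abs(rng.normal(0.0, baseline_log2_sd, size=int(offtarget.sum())))
    )

    counts = np.zeros((n_genes, len(design)), dtype=np.int64)
    libs = np.zeros(len(design), dtype=np.int64)
    cell_pi: dict[tuple[str, str], np.ndarray] = {}
    for j, (sample_id, row) in enumerate(design.iterrows()):
        key = (row["genotype"], row["treatment"])
        if key not in cell_pi:
            mult = np.ones(n_genes)
            if row["treatment"] == "ethanol":
                if row["genotype"] == "iTPS":
                    mult = np.exp2(fc)
                else:  # alcR: only the off-target component responds
                    mult = np.where(offtarget, np.exp2(fc), 1.0)
            abundance = base * mult
            pi = mapped_fraction * abundance / base.sum()
            if pi.sum() >= 0.95:
                raise ValueError(
                    "planted shifts push the simulated genes above 95% of the "
                    "library; lower mapped_fraction or effect sizes"
                )
            cell_pi[key] = pi
        pi = cell_pi[key]
        lib = int(rng.integers(int(depth * 0.8), int(depth * 1.2) + 1))
        if theta == 0:
            p_rep = pi
        elif noise_model == "betabinomial":
            s = 1.0 / theta - 1.0
            p_rep = rng.beta(pi * s, (1.0 - pi) * s)
        else:
            # log-normal extra-variance with matched coefficient of variation
            cv = np.sqrt(theta * (1.0 - pi) / pi)
            sigma = np.sqrt(np.log1p(cv**2))
            p_rep = pi * rng.lognormal(-(sigma**2) / 2.0, sigma)
            p_rep = np.clip(p_rep, 0.0, 1.0)
        counts[:, j] = rng.binomial(lib, p_rep)
        libs[j] = lib

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=design.index),
        samples=design.copy(),
        library_sizes=pd.Series(libs, index=design.index, name="library_size"),
    )
    return cm


def generate_panel(
    truth: TruthTable,
    k_contrasts: int | None = None,
    noise_sd: float = 0.15,
    missing_rate: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed reference panel: truth plus noise, with cells dropped at
    ``missing_rate`` (missing is NaN, never 0)."""
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if k_contrasts is None:
        k_contrasts = truth.panel.shape[1]
    if k_contrasts != truth.panel.shape[1]:
        raise ValueError(
            f"truth was planted with K={truth.panel.shape[1]} contrasts, "
            f"requested {k_contrasts}"
        )
    rng = np.random.default_rng(seed)
    values = truth.panel.to_numpy() + rng.normal(0.0, noise_sd, size=truth.panel.shape)
    if missing_rate > 0:
        values = np.where(rng.random(values.shape) < missing_rate, np.nan, values)
    return pd.DataFrame(values, index=truth.panel.index, columns=truth.panel.columns)


def generate_external(
    truth: TruthTable,
    mode: str = "reciprocal",
    noise_sd: float = 0.1,
    seed: int = 0,
    frac_opposite: float = 0.75,
) -> pd.Series:
    """External response signature joined by gene id.

    ``reciprocal`` mirrors a SnRK1-like signature: opposite to the planted
    response for direct genes, concordant for indirect genes (high Tre6P
    inhibits SnRK1, low sugar activates it).  ``concordant`` matches the
    planted response for all responsive genes; ``mixed`` plants a
    ``frac_opposite`` / (1 - frac_opposite) opposite/same split among
    responsive genes.  Everything else is pure noise.
    """
    rng = np.random.default_rng(seed)
    table = truth.table
    fc = table["true_itps_log2fc"].to_numpy()
    cls = table["gene_class"].to_numpy()
    responsive = np.isin(cls, ("direct", "indirect", "orthogonal"))
    base = np.zeros(len(table))
    if mode == "reciprocal":
        base[cls == "direct"] = -fc[cls == "direct"]
        base[cls == "indirect"] = fc[cls == "indirect"]
    elif mode == "concordant":
        base[responsive] = fc[responsive]
    elif mode == "mixed":
        flip = rng.random(len(table)) < frac_opposite
        base[responsive] = np.where(flip[responsive], -fc[responsive], fc[responsive])
    else:
        raise ValueError(f"unknown external mode {mode!r}")
    noise = rng.normal(0.0, noise_sd, size=len(table)) if noise_sd > 0 else 0.0
    external = pd.Series(base + noise, index=table.index, name="log2_fc")
    return external


def simulate_null_groups(
    n_genes: int,
    n_replicates: int = 4,
    p0: float = 0.1,
    theta: float = 0.005,
    depth: float = 2e5,
    seed: int = 0,
):
    """Calibration null for the weighted proportions test.

    Draws two identically distributed replicated groups of beta-binomial
    counts per gene (no planted effects) and returns (xA, nA, xB, nB)
    arrays of shape (n_genes, n_replicates).  Genes are drawn marginally at
    a common well-measured proportion ``p0`` — this is a statistical
    harness for type-I-error and p-value-uniformity checks, not a coherent
    transcriptome.  Library sizes vary +-20% around ``depth``.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    rng = np.random.default_rng(seed)

    def draw():
        n = rng.integers(int(depth * 0.8), int(depth * 1.2) + 1, size=(n_genes, n_replicates))
        if theta == 0:
            p = np.full((n_genes, n_replicates), p0)
        else:
            s = 1.0 / theta - 1.0
            p = rng.beta(p0 * s, (1.0 - p0) * s, size=(n_genes, n_replicates))
        return rng.binomial(n, p), n

    xA, nA = draw()
    xB, nB = draw()
    return xA, nA, xB, nB


def generate_lengths(gene_ids, seed: int = 0) -> pd.Series:
    """Synthetic transcript lengths, 500-3000 bp."""
    rng = np.random.default_rng(seed)
    lengths = rng.integers(500, 3001, size=len(gene_ids))
    return pd.Series(lengths, index=pd.Index(gene_ids, name="gene_id"), name="length")


@dataclasses.dataclass
class SyntheticDataset:
    """All pipeline inputs for one simulated experiment."""

    truth: TruthTable
    counts: CountMatrix
    lengths: pd.Series
    panel: pd.DataFrame
    external: pd.Series
    binmap: BINMap


def simulate_all(
    n_genes: int = 2000,
    seed: int = 7,
    fractions=DEFAULT_FRACTIONS,
    effect_scale: float = 1.0,
    k_contrasts: int = 9,
    timepoints=("4h",),
    n_replicates: int = 4,
    depth: float = 2e7,
    theta: float = 2.5e-7,
    panel_noise_sd: float = 0.15,
    panel_missing_rate: float = 0.1,
    external_mode: str = "reciprocal",
    external_noise_sd: float = 0.1,
) -> SyntheticDataset:
    """Generate a complete, internally consistent synthetic experiment.

    Sub-seeds for each stage are derived deterministically from ``seed``, so
    the whole dataset is reproducible from a single integer.
    """
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(5)]
    truth = generate_truth(
        n_genes, fractions=fractions, effect_scale=effect_scale,
        seed=sub[0], k_contrasts=k_contrasts,
    )
    design = default_design(timepoints=timepoints, n_replicates=n_replicates)
    counts = generate_counts(truth, design=design, depth=depth, theta=theta, seed=sub[1])
    panel = generate_panel(
        truth, noise_sd=panel_noise_sd, missing_rate=panel_missing_rate, seed=sub[2]
    )
    external = generate_external(
        truth, mode=external_mode, noise_sd=external_noise_sd, seed=sub[3]
    )
    truth.table["true_external_log2fc"] = external
    lengths = generate_lengths(truth.gene_ids, seed=sub[4])
    binmap = generate_binmap(truth)
    return SyntheticDataset(
        truth=truth, counts=counts, lengths=lengths,
        panel=panel, external=external, binmap=binmap,
    )
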