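"""Synthetic-data generator: tetraploid meiosis, crossing designs, marker
scoring, and phenotypes with family structure.

Gametes of a subgenome-duplex tetraploid (two G and two N chromosomes at a
locus) are drawn at the class level of the preferential-pairing model: GN
gametes with probability f_GN(p, alpha) and GG / NN gametes splitting the
remainder equally, with tagged within-class compositions uniform.  Genotypes
that are not subgenome-duplex (which arise in selfed lineages once an allele
class is lost) fall back to random chromosome assortment of their four
tagged alleles, since preferential pairing between subgenomes is undefined
for them.  Loci are independent (one marker per linkage group).

Phenotypes are built from a dosage (additive) effect per G allele, a
dominance bonus for carrying both subgenomes at a locus, and normal family,
maternal-line, and residual deviates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import MarkerObservation
from .pairing import P_MAX, wu_gn_frequency

__all__ = [
    "Allele",
    "TetraploidGenotype",
    "WuModelParams",
    "LineageDesign",
    "PhenotypeModel",
    "F1_DUPLEX",
    "TESTER_NNNN",
    "simulate_gametes",
    "simulate_cross",
    "simulate_lineages",
    "simulate_marker_panel",
    "collapse_to_marker_calls",
    "simulate_phenotypes",
    "simulate_family_structure",
    "simulate_diploid_f2_study",
]


Allele = tuple[str, int]  # (subgenome "G"/"N", founder copy 1/2)


@dataclass(frozen=True)
class WuModelParams:
    """Preferential pairing factor p in [0, 2/3] and double reduction rate alpha."""

    p: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= float(P_MAX) + 1e-12:
            raise ValueError(f"p={self.p} outside [0, 2/3]")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha={self.alpha} outside [0, 1]")

    @property
    def f_gn(self) -> float:
        return wu_gn_frequency(self.p, self.alpha)


@dataclass(frozen=True)
class TetraploidGenotype:
    """Four tagged alleles at one locus; founder tags survive simulated meioses."""

    alleles: tuple[Allele, Allele, Allele, Allele]

    def __post_init__(self) -> None:
        if len(self.alleles) != 4:
            raise ValueError("a tetraploid genotype carries exactly four alleles")

    @property
    def g_dose(self) -> int:
        return sum(1 for sub, _ in self.alleles if sub == "G")

    @property
    def is_duplex(self) -> bool:
        return self.g_dose == 2

    @property
    def is_het(self) -> bool:
        """Carries at least one allele from each subgenome (band from each parent)."""
        return 0 < self.g_dose < 4


F1_DUPLEX = TetraploidGenotype((("G", 1), ("G", 2), ("N", 1), ("N", 2)))
TESTER_NNNN = TetraploidGenotype((("N", 1), ("N", 1), ("N", 2), ("N", 2)))

# within-class index pairs for a duplex parent: positions of the two same-class
# alleles; double-reduction products reuse one position twice
_SAME_CLASS_PAIRS = ((0, 0), (0, 1), (1, 1))


def _draw_gamete(
    genotype: TetraploidGenotype, params: WuModelParams, rng: np.random.Generator
) -> tuple[Allele, Allele]:
    alleles = genotype.alleles
    g_idx = [i for i, (sub, _) in enumerate(alleles) if sub == "G"]
    n_idx = [i for i, (sub, _) in enumerate(alleles) if sub == "N"]
    if len(g_idx) == 2:
        f = params.f_gn
        u = rng.random()
        if u < f:  # balanced GN gamete: one allele of each subgenome
            return (
                alleles[g_idx[rng.integers(2)]],
                alleles[n_idx[rng.integers(2)]],
            )
        pool = g_idx if u < f + (1.0 - f) / 2.0 else n_idx
        a, b = _SAME_CLASS_PAIRS[rng.integers(3)]
        return (alleles[pool[a]], alleles[pool[b]])
    # non-duplex: random chromosome assortment — two distinct chromosomes
    i = rng.integers(4)
    j = (i + 1 + rng.integers(3)) % 4
    return (alleles[i], alleles[j])


def simulate_gametes(
    parent: TetraploidGenotype,
    params: WuModelParams,
    n: int,
    seed: "int | np.random.Generator",
) -> pd.Series:
    """Draw ``n`` gametes from a duplex parent; counts per tagged gamete type.

    Class counts are multinomial at the model frequencies (GN: f_GN, GG and
    NN: (1 − f_GN)/2 each); tagged compositions within a class are uniform.
    Returns a Series indexed by sorted allele-pair labels such as "G1/N2".
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not parent.is_duplex:
        raise ValueError("class-level gamete counts are defined for duplex parents")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f = params.f_gn
    n_gn, n_gg, n_nn = rng.multinomial(n, [f, (1 - f) / 2, (1 - f) / 2])
    g_alleles = [a for a in parent.alleles if a[0] == "G"]
    n_alleles = [a for a in parent.alleles if a[0] == "N"]

    def label(a: Allele, b: Allele) -> str:
        pair = sorted([f"{a[0]}{a[1]}", f"{b[0]}{b[1]}"])
        return "/".join(pair)

    counts: dict[str, int] = {}
    # GN: uniform over the 4 cross pairs
    gn_pairs = [(ga, na) for ga in g_alleles for na in n_alleles]
    for pair, c in zip(gn_pairs, rng.multinomial(n_gn, [0.25] * 4)):
        counts[label(*pair)] = counts.get(label(*pair), 0) + int(c)
    # GG / NN: uniform over the 3 same-class compositions
    for pool, total in ((g_alleles, n_gg), (n_alleles, n_nn)):
        comps = [(pool[a], pool[b]) for a, b in _SAME_CLASS_PAIRS]
        for pair, c in zip(comps, rng.multinomial(total, [1 / 3] * 3)):
            counts[label(*pair)] = counts.get(label(*pair), 0) + int(c)
    return pd.Series(counts, dtype=int).sort_index()


def simulate_cross(
    maternal: TetraploidGenotype,
    paternal: TetraploidGenotype,
    params: WuModelParams,
    n_offspring: int,
    seed: "int | np.random.Generator",
) -> list[TetraploidGenotype]:
    """Offspring genotypes from independent gamete draws of each parent."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = []
    for _ in range(n_offspring):
        gm = _draw_gamete(maternal, params, rng)
        gp = _draw_gamete(paternal, params, rng)
        out.append(TetraploidGenotype(gm + gp))
    return out


def collapse_to_marker_calls(
    genotypes_by_locus: "dict[str, Sequence[TetraploidGenotype]]",
) -> list[MarkerObservation]:
    """Score genotypes as heterozygous / allele-loss per marker.

    HET means at least one allele from each subgenome; LOSS means all four
    alleles from the N subgenome (the G band lost) or all four from G.
    """
    out = []
    for marker_id, genos in genotypes_by_locus.items():
        n = len(genos)
        het = sum(1 for g in genos if g.is_het)
        out.append(
            MarkerObservation(
                marker_id=str(marker_id), n_scored=n, n_het=het, n_loss=n - het
            )
        )
    return out


def simulate_marker_panel(
    params: WuModelParams,
    n_progeny: int,
    n_markers: int,
    seed: "int | np.random.Generator",
) -> list[MarkerObservation]:
    """Backcross marker panel at the aggregate level.

    Each backcross offspring is a quadruple homozygote exactly when the
    duplex parent's gamete was NN, so per marker the loss count is binomial
    with probability (1 − f_GN)/2; this is the count-level shortcut for
    ``simulate_cross`` + ``collapse_to_marker_calls`` on the F1 × tester
    design, and is what large parameter-recovery experiments use.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p_loss = (1.0 - params.f_gn) / 2.0
    losses = rng.binomial(n_progeny, p_loss, size=n_markers)
    return [
        MarkerObservation(
            marker_id=f"sim_{i}",
            n_scored=n_progeny,
            n_het=int(n_progeny - k),
            n_loss=int(k),
        )
        for i, k in enumerate(losses)
    ]


# ---------------------------------------------------------------------------
# lineage designs


@dataclass(frozen=True)
class LineageDesign:
    """Selfed-lineage crossing design: S-lines kept by single-seed descent,
    split into maternal sublines at the penultimate generation.

    Defaults mirror the study design: 48 S-lines per cross direction selfed
    to S4, 43 (G-maternal) or 35 (N-maternal) families surviving, two
    maternal lines per family, three measured individuals each.
    """

    generations_of_selfing: int = 4
    n_families: int = 48
    surviving_families: int | None = 43
    maternal_lines_per_family: int = 2
    individuals_per_maternal_line: int = 3
    cross_direction: str = "G"
    n_loci: int = 13

    def __post_init__(self) -> None:
        if min(
            self.n_families,
            self.maternal_lines_per_family,
            self.individuals_per_maternal_line,
            self.n_loci,
        ) < 1:
            raise ValueError("design counts must be >= 1")
        if self.generations_of_selfing < 0:
            raise ValueError("generations_of_selfing must be >= 0")


def _self_offspring(
    parent_loci: "list[TetraploidGenotype]",
    params: WuModelParams,
    rng: np.random.Generator,
) -> "list[TetraploidGenotype]":
    return [
        TetraploidGenotype(_draw_gamete(g, params, rng) + _draw_gamete(g, params, rng))
        for g in parent_loci
    ]


def simulate_lineages(
    design: LineageDesign,
    params: WuModelParams,
    seed: "int | np.random.Generator",
) -> pd.DataFrame:
    """Iterated selfing of F1-derived S-lines with single-seed descent.

    Returns a long table with one row per individual per generation carrying
    the G-allele dose and band-heterozygosity per locus.  Generation g rows
    are the S_g individuals; at the final generation each surviving family
    contributes ``maternal_lines_per_family × individuals_per_maternal_line``
    measured plants (sublines split at the penultimate generation).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    founder = [F1_DUPLEX] * design.n_loci
    rows = []

    def record(gen, family, maternal, indiv, loci):
        row = {
            "generation": gen,
            "family": f"{design.cross_direction}{family:03d}",
            "maternal_line": maternal,
            "individual": indiv,
        }
        for j, g in enumerate(loci):
            row[f"dose_{j}"] = g.g_dose
            row[f"het_{j}"] = int(g.is_het)
        rows.append(row)

    n_keep = (
        design.surviving_families
        if design.surviving_families is not None
        else design.n_families
    )
    n_keep = min(n_keep, design.n_families)
    g_total = design.generations_of_selfing
    split_gen = max(g_total - 1, 1)  # penultimate generation: subline split

    for fam in range(design.n_families):
        lineage = founder
        if g_total == 0:
            record(0, fam, "a", 0, lineage)
            continue
        keep_family = fam < n_keep
        for gen in range(1, g_total + 1):
            if gen < split_gen or not keep_family:
                lineage = _self_offspring(lineage, params, rng)
                record(gen, fam, "a", 0, lineage)
                if not keep_family and gen == split_gen:
                    break
            elif gen == split_gen:
                sublines = {
                    chr(ord("a") + m): _self_offspring(lineage, params, rng)
                    for m in range(design.maternal_lines_per_family)
                }
                for name, loci in sublines.items():
                    record(gen, fam, name, 0, loci)
            else:  # final generation: measured individuals per subline
                for name, loci in sublines.items():
                    for i in range(design.individuals_per_maternal_line):
                        record(gen, fam, name, i, _self_offspring(loci, params, rng))
        # unsurviving families are dropped after the marker generation
    df = pd.DataFrame(rows)
    return df


# ---------------------------------------------------------------------------
# phenotypes


@dataclass(frozen=True)
class PhenotypeModel:
    """Trait model: baseline, per-G-allele dosage effect, per-locus dominance
    bonus for carrying both subgenomes, and family / maternal / residual
    variance components (trait units squared)."""

    mu: float = 0.0
    additive_effect: float = 0.0
    dominance_effect: float = 0.0
    n_loci: int = 1
    var_family: float = 0.0
    var_maternal: float = 0.0
    var_residual: float = 0.0

    def __post_init__(self) -> None:
        if min(self.var_family, self.var_maternal, self.var_residual) < 0:
            raise ValueError("variance components must be >= 0")


def genetic_value(
    dose: np.ndarray, het: np.ndarray, model: PhenotypeModel
) -> np.ndarray:
    """Deterministic genetic value from per-locus dose and heterozygosity arrays."""
    return (
        model.mu
        + model.additive_effect * dose.sum(axis=-1)
        + model.dominance_effect * het.sum(axis=-1)
    )


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    model: PhenotypeModel,
    seed: "int | np.random.Generator",
    trait_name: str = "trait",
) -> pd.DataFrame:
    """Attach one simulated trait to a genotype table.

    ``genotypes`` must carry ``family`` and ``maternal_line`` columns plus
    ``dose_*`` / ``het_*`` locus columns (as produced by
    :func:`simulate_lineages`).  trait = mu + additive·Σdose + dominance·Σhet
    + family + maternal + residual normal deviates.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dose_cols = sorted(c for c in genotypes.columns if c.startswith("dose_"))
    het_cols = sorted(c for c in genotypes.columns if c.startswith("het_"))
    dose = genotypes[dose_cols].to_numpy(dtype=float) if dose_cols else np.zeros((len(genotypes), 0))
    het = genotypes[het_cols].to_numpy(dtype=float) if het_cols else np.zeros((len(genotypes), 0))
    value = genetic_value(dose, het, model)

    fam_keys = genotypes["family"].astype(str)
    mat_keys = fam_keys + "/" + genotypes["maternal_line"].astype(str)
    fam_levels = pd.unique(fam_keys)
    mat_levels = pd.unique(mat_keys)
    fam_dev = dict(
        zip(fam_levels, rng.normal(0.0, np.sqrt(model.var_family), len(fam_levels)))
    )
    mat_dev = dict(
        zip(mat_levels, rng.normal(0.0, np.sqrt(model.var_maternal), len(mat_levels)))
    )
    resid = rng.normal(0.0, np.sqrt(model.var_residual), len(genotypes))

    out = genotypes[["family", "maternal_line"]].copy()
    if "class_label" in genotypes.columns:
        out["class_label"] = genotypes["class_label"]
    out[trait_name] = (
        value
        + fam_keys.map(fam_dev).to_numpy()
        + mat_keys.map(mat_dev).to_numpy()
        + resid
    )
    return out


def simulate_family_structure(
    n_families: int,
    n_maternal: int,
    n_individuals: int,
    var_family: float,
    var_maternal: float,
    var_residual: float,
    mu: float = 0.0,
    seed: "int | np.random.Generator" = 0,
    trait_name: str = "trait",
) -> pd.DataFrame:
    """Balanced nested phenotype table with pure variance-component structure
    (no segregating genetic effects) — the null workload for the nested
    variance-component estimator."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fam = np.repeat(np.arange(n_families), n_maternal * n_individuals)
    mat = np.tile(np.repeat(np.arange(n_maternal), n_individuals), n_families)
    value = (
        mu
        + np.repeat(rng.normal(0, np.sqrt(var_family), n_families), n_maternal * n_individuals)
        + np.repeat(
            rng.normal(0, np.sqrt(var_maternal), n_families * n_maternal), n_individuals
        )
        + rng.normal(0, np.sqrt(var_residual), fam.size)
    )
    return pd.DataFrame(
        {
            "family": [f"F{i:03d}" for i in fam],
            "maternal_line": [chr(ord("a") + m) for m in mat],
            trait_name: value,
        }
    )


def simulate_diploid_f2_study(
    model: PhenotypeModel,
    n_f2: int,
    n_parental: int = 100,
    seed: "int | np.random.Generator" = 0,
) -> dict[str, np.ndarray]:
    """Diploid control cross: parental lines, F1, and a segregating F2.

    Parents are fixed for opposite alleles at every locus, the F1 is
    uniformly heterozygous, and each F2 locus segregates 1 AA : 2 Aa : 1 aa
    independently.  Dose counts the high-value parental allele (0-2);
    dominance adds its bonus to heterozygous loci.  Only the residual
    variance component applies (single common-garden generation).
    Returns trait arrays keyed by class: P1, P2, F1, F2.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    L = model.n_loci

    def pheno(dose: np.ndarray) -> np.ndarray:
        het = (dose == 1).astype(float)
        value = (
            model.mu
            + model.additive_effect * dose.sum(axis=1)
            + model.dominance_effect * het.sum(axis=1)
        )
        return value + rng.normal(0, np.sqrt(model.var_residual), dose.shape[0])

    return {
        "P1": pheno(np.full((n_parental, L), 2)),
        "P2": pheno(np.full((n_parental, L), 0)),
        "F1": pheno(np.full((n_parental, L), 1)),
        "F2": pheno(rng.binomial(2, 0.5, size=(n_f2, L))),
    }
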