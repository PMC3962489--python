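"""Single-locus chromosome-pairing models for a duplex tetraploid.

An allotetraploid F1 carries two chromosomes from each progenitor subgenome
(G1, G2, N1, N2 — a duplex, AAaa-type genotype at every marker).  How those
four chromosomes pair at meiosis determines the gametic ratio at a marker
and hence the genotype distribution of selfed (F2-type) or backcross
progeny.  Five classical models are encoded here, from strict homologous
bivalent pairing (disomic inheritance, fixed heterozygosity) to tetrasomic
models allowing double reduction:

======================  ==========  ================
model                   inheritance gametic ratio
======================  ==========  ================
HOMOLOG_DISOMIC         disomic     0 AA : 1 Aa : 0 aa
HOMEOLOG_DISOMIC        disomic     1 AA : 2 Aa : 1 aa
RANDOM_CHROMOSOME       either      1 AA : 4 Aa : 1 aa
RANDOM_CHROMATID        tetrasomic  3 AA : 8 Aa : 3 aa
MAX_EQUATIONAL          tetrasomic  2 AA : 5 Aa : 2 aa
======================  ==========  ================

Ratios are stored as exact rationals.  Independent enumeration oracles are
provided for the random-chromosome and random-chromatid models; the
maximal-equational ratio is taken as given (its derivation enumerates nine
quadrivalent configurations not reproduced here).

The continuous bridge between the disomic and tetrasomic extremes is the
preferential pairing factor ``p`` in [0, 2/3] together with the double
reduction rate ``alpha``: ``wu_gn_frequency`` gives the expected frequency
of balanced GN gametes as a function of (p, alpha).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

__all__ = [
    "PairingModel",
    "ProgenyDesign",
    "GameteClassDistribution",
    "GenotypeDistribution",
    "gamete_ratios",
    "progeny_genotype_frequencies",
    "expected_apparent_heterozygosity",
    "enumerate_random_chromosome",
    "enumerate_random_chromatid",
    "wu_gn_frequency",
    "P_MAX",
    "pairing_model_table",
]

#: upper bound of the preferential pairing factor (strict homologous bivalents)
P_MAX = Fraction(2, 3)


class PairingModel(enum.Enum):
    """The five named single-locus pairing models."""

    HOMOLOG_DISOMIC = "homolog-disomic"
    HOMEOLOG_DISOMIC = "homeolog-disomic"
    RANDOM_CHROMOSOME = "random-chromosome"
    RANDOM_CHROMATID = "random-chromatid"
    MAX_EQUATIONAL = "max-equational"

    @classmethod
    def parse(cls, name: "str | PairingModel") -> "PairingModel":
        if isinstance(name, cls):
            return name
        key = str(name).strip().lower().replace("_", "-")
        for member in cls:
            if member.value == key or member.name.lower().replace("_", "-") == key:
                return member
        raise ValueError(
            f"unknown pairing model {name!r}; expected one of "
            + ", ".join(m.value for m in cls)
        )


class ProgenyDesign(enum.Enum):
    """Progeny design: selfing of the F1, or backcross to a quadruplex-recessive tester."""

    SELF = "self"
    BACKCROSS_TO_RECESSIVE = "backcross"


# exact Table ratios: (AA, Aa, aa) counts over the stated denominator
_RATIOS: dict[PairingModel, tuple[int, int, int]] = {
    PairingModel.HOMOLOG_DISOMIC: (0, 1, 0),
    PairingModel.HOMEOLOG_DISOMIC: (1, 2, 1),
    PairingModel.RANDOM_CHROMOSOME: (1, 4, 1),
    PairingModel.RANDOM_CHROMATID: (3, 8, 3),
    PairingModel.MAX_EQUATIONAL: (2, 5, 2),
}


@dataclass(frozen=True)
class GameteClassDistribution:
    """Frequencies of the three single-locus gamete classes of a duplex parent.

    ``f_AA`` / ``f_Aa`` / ``f_aa`` are the probabilities that a gamete carries
    two, one, or zero copies of the A (G-subgenome) allele.  Stored as exact
    :class:`~fractions.Fraction` where constructed from model ratios.
    """

    f_AA: Fraction | float
    f_Aa: Fraction | float
    f_aa: Fraction | float

    def __post_init__(self) -> None:
        total = self.f_AA + self.f_Aa + self.f_aa
        if abs(float(total) - 1.0) > 1e-12:
            raise ValueError(f"gamete class frequencies sum to {float(total)}, not 1")
        if any(float(f) < -1e-15 for f in self):
            raise ValueError("gamete class frequencies must be nonnegative")

    def __iter__(self):
        return iter((self.f_AA, self.f_Aa, self.f_aa))

    @property
    def doses(self) -> tuple[int, int, int]:
        """A-allele dose contributed by each class."""
        return (2, 1, 0)


#: gamete distribution contributed by the recessive (NNNN / aaaa) tester
TESTER_GAMETES = GameteClassDistribution(Fraction(0), Fraction(0), Fraction(1))


@dataclass(frozen=True)
class GenotypeDistribution:
    """Frequencies of the five zygotic dosage classes AAAA..aaaa (dose 4..0)."""

    f4: Fraction | float
    f3: Fraction | float
    f2: Fraction | float
    f1: Fraction | float
    f0: Fraction | float

    def __post_init__(self) -> None:
        total = self.f4 + self.f3 + self.f2 + self.f1 + self.f0
        if abs(float(total) - 1.0) > 1e-12:
            raise ValueError(f"genotype frequencies sum to {float(total)}, not 1")
        if any(float(f) < -1e-15 for f in self):
            raise ValueError("genotype frequencies must be nonnegative")

    def __iter__(self):
        return iter((self.f4, self.f3, self.f2, self.f1, self.f0))

    def by_dose(self, dose: int):
        return (self.f0, self.f1, self.f2, self.f3, self.f4)[dose]


def gamete_ratios(model: "PairingModel | str") -> GameteClassDistribution:
    """Exact gametic ratio of the duplex F1 under a named pairing model."""
    model = PairingModel.parse(model)
    a, h, b = _RATIOS[model]
    denom = a + h + b
    return GameteClassDistribution(
        Fraction(a, denom), Fraction(h, denom), Fraction(b, denom)
    )


def progeny_genotype_frequencies(
    gametes_maternal: GameteClassDistribution,
    gametes_paternal: GameteClassDistribution,
) -> GenotypeDistribution:
    """Convolve maternal and paternal gamete dosage classes into zygotic dosage 0-4.

    For a selfed design pass the same distribution twice; for a backcross to
    the quadruplex-recessive tester pass :data:`TESTER_GAMETES` on one side.
    """
    freq: dict[int, Fraction | float] = {d: Fraction(0) for d in range(5)}
    for fm, dm in zip(gametes_maternal, gametes_maternal.doses):
        for fp, dp in zip(gametes_paternal, gametes_paternal.doses):
            freq[dm + dp] += fm * fp
    return GenotypeDistribution(freq[4], freq[3], freq[2], freq[1], freq[0])


def genotype_distribution(
    model: "PairingModel | str", design: ProgenyDesign
) -> GenotypeDistribution:
    """Progeny genotype distribution for a model/design pair."""
    g = gamete_ratios(model)
    other = g if design is ProgenyDesign.SELF else TESTER_GAMETES
    return progeny_genotype_frequencies(g, other)


def expected_apparent_heterozygosity(
    genotypes: GenotypeDistribution, design: ProgenyDesign
) -> Fraction | float:
    """Expected fraction of progeny showing a marker band from each parent.

    Any individual with at least one allele from each subgenome scores as
    (apparently) heterozygous, so only the quadruple homozygotes are excluded:
    both homozygous classes under selfing, and only the recessive class under
    the backcross (the dominant quadruple homozygote is unreachable there).
    """
    if design is ProgenyDesign.SELF:
        return 1 - genotypes.f4 - genotypes.f0
    return 1 - genotypes.f0


def quadruple_homozygote_frequency(
    model: "PairingModel | str", design: ProgenyDesign
) -> Fraction | float:
    """Frequency of detectable quadruple homozygotes under a model/design.

    Under selfing both GGGG and NNNN reveal non-homologous segregation; in the
    backcross to the recessive tester only NNNN can occur.
    """
    geno = genotype_distribution(model, design)
    if design is ProgenyDesign.SELF:
        return geno.f4 + geno.f0
    return geno.f0


# ---------------------------------------------------------------------------
# enumeration oracles


def enumerate_random_chromosome(
    partitions: str = "all",
) -> GameteClassDistribution:
    """Brute-force oracle for random chromosome (bivalent) assortment.

    Enumerates the three ways of partitioning the four chromosomes
    {G1, G2, N1, N2} into two bivalents; each bivalent then sends one of its
    two chromosomes to the gamete, uniformly and independently.

    Parameters
    ----------
    partitions : {"all", "homolog", "homeolog"}
        Restrict the enumeration to the homologous partition
        ({G1,G2}|{N1,N2}), to the two homeologous partitions, or use all
        three with equal weight (the random-bivalent model).
    """
    chroms = ("G1", "G2", "N1", "N2")
    all_partitions = []
    for mate in range(1, 4):  # partner of chroms[0]
        pair1 = (chroms[0], chroms[mate])
        pair2 = tuple(c for c in chroms if c not in pair1)
        all_partitions.append((pair1, pair2))

    def is_homolog(part):
        (a, b), _ = part
        return a[0] == b[0]

    if partitions == "homolog":
        chosen = [p for p in all_partitions if is_homolog(p)]
    elif partitions == "homeolog":
        chosen = [p for p in all_partitions if not is_homolog(p)]
    elif partitions == "all":
        chosen = all_partitions
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown partition restriction {partitions!r}")

    counts = {2: 0, 1: 0, 0: 0}
    n_outcomes = 0
    for pair1, pair2 in chosen:
        for c1 in pair1:
            for c2 in pair2:
                dose = (c1[0] == "G") + (c2[0] == "G")
                counts[dose] += 1
                n_outcomes += 1
    return GameteClassDistribution(
        Fraction(counts[2], n_outcomes),
        Fraction(counts[1], n_outcomes),
        Fraction(counts[0], n_outcomes),
    )


def enumerate_random_chromatid(allow_sister: bool = True) -> GameteClassDistribution:
    """Brute-force oracle for random chromatid assortment.

    After replication the duplex parent carries 8 chromatids, 4 per allele.
    A gamete is an unordered pair of distinct chromatids drawn uniformly.
    Sister (and homolog-derived identical) pairs model double reduction;
    excluding pairs from the same chromosome collapses the result to the
    random-chromosome ratio.
    """
    # chromatids tagged (chromosome index, allele); chromosomes 0,1 carry A
    chromatids = [(chrom, "A" if chrom < 2 else "a") for chrom in range(4) for _ in range(2)]
    counts = {2: 0, 1: 0, 0: 0}
    n_pairs = 0
    for (c1, a1), (c2, a2) in itertools.combinations(chromatids, 2):
        if not allow_sister and c1 == c2:
            continue
        dose = (a1 == "A") + (a2 == "A")
        counts[dose] += 1
        n_pairs += 1
    return GameteClassDistribution(
        Fraction(counts[2], n_pairs),
        Fraction(counts[1], n_pairs),
        Fraction(counts[0], n_pairs),
    )


# ---------------------------------------------------------------------------
# preferential pairing / double reduction model


def _validate_params(p: float, alpha: float) -> None:
    if not 0.0 <= p <= float(P_MAX) + 1e-12:
        raise ValueError(f"preferential pairing factor p={p} outside [0, 2/3]")
    if alpha < 0:
        raise ValueError(f"double reduction rate alpha={alpha} must be >= 0")


def wu_double_reduction_frequency(p: float, alpha: float) -> float:
    """Total frequency of double-reduction gametes (G1G1-type), α·(2/3 − 3/2·p²)."""
    _validate_params(p, alpha)
    return alpha * (2.0 / 3.0 - 1.5 * p * p)


def wu_gn_frequency(p: float, alpha: float = 0.0) -> float:
    """Expected frequency of balanced GN gametes from a duplex parent.

    Evaluates, for preferential pairing factor ``p`` and double reduction
    rate ``alpha``,

        f_GN = 2/9 + p/3 + 5/4·p² + 2/3·(2/3 − 3/2·p² − α·(2/3 − 3/2·p²))

    which for ``alpha = 0`` simplifies to ``2/3 + p/3 + p²/4``: strictly
    increasing on [0, 2/3], equal to 2/3 at p=0 (fully random pairing) and
    1 at p=2/3 (strict homologous bivalents, fixed heterozygosity).
    """
    _validate_params(p, alpha)
    dr = wu_double_reduction_frequency(p, alpha)
    f = (
        2.0 / 9.0
        + p / 3.0
        + 1.25 * p * p
        + (2.0 / 3.0) * (2.0 / 3.0 - 1.5 * p * p - dr)
    )
    return min(max(f, 0.0), 1.0)


def wu_gamete_distribution(p: float, alpha: float = 0.0) -> GameteClassDistribution:
    """Gamete class distribution (GG, GN, NN) under the (p, alpha) model.

    GG and NN gametes are assumed equally frequent by the symmetry of the
    duplex parent, so each receives half of ``1 − f_GN``.
    """
    f_gn = wu_gn_frequency(p, alpha)
    off = (1.0 - f_gn) / 2.0
    return GameteClassDistribution(off, f_gn, off)


# ---------------------------------------------------------------------------
# tabulation


def pairing_model_table(as_float: bool = False) -> "list[dict]":
    """Rows of the model summary table: ratios, progeny frequencies, expected
    apparent heterozygosity for selfed and backcross designs."""
    rows = []
    for model in PairingModel:
        g = gamete_ratios(model)
        f2 = progeny_genotype_frequencies(g, g)
        bc = progeny_genotype_frequencies(g, TESTER_GAMETES)
        het_f2 = expected_apparent_heterozygosity(f2, ProgenyDesign.SELF)
        het_bc = expected_apparent_heterozygosity(bc, ProgenyDesign.BACKCROSS_TO_RECESSIVE)
        fmt = (lambda x: float(x)) if as_float else (lambda x: x)
        rows.append(
            {
                "model": model.value,
                "gamete_AA": fmt(g.f_AA),
                "gamete_Aa": fmt(g.f_Aa),
                "gamete_aa": fmt(g.f_aa),
                "f2_genotypes": tuple(fmt(x) for x in f2),
                "bc1_genotypes": tuple(fmt(x) for x in bc),
                "apparent_het_f2": fmt(het_f2),
                "apparent_het_bc1": fmt(het_bc),
            }
        )
    return rows
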