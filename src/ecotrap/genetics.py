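"""Z-linked one-locus/two-allele oviposition-preference genetics.

Females are the heterogametic sex (ZW), so a female carries a single Z
allele — inherited from her father — and it alone determines whether she
will oviposit on the non-native host.  Males (ZZ) carry two alleles and have
no oviposition phenotype.  Allele frequencies are therefore computed per sex
and pooled as (2*p_male + p_female)/3, reflecting that two thirds of the Z
chromosomes in the population reside in males.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

REJECT = 0
ACCEPT = 1


class Sex(IntEnum):
    MALE = 0
    FEMALE = 1


@dataclass(frozen=True)
class Genotype:
    """A sexed Z-locus genotype: one allele for females (plus the implicit W),
    an unordered pair for males (stored in canonical sorted order)."""

    sex: Sex
    z1: int
    z2: int | None = None

    def __post_init__(self):
        if self.z1 not in (REJECT, ACCEPT):
            raise ValueError(f"invalid allele {self.z1!r}")
        if self.sex == Sex.FEMALE:
            if self.z2 is not None:
                raise ValueError("a female carries exactly one Z allele")
        else:
            if self.z2 not in (REJECT, ACCEPT):
                raise ValueError("a male carries exactly two Z alleles")
            if self.z1 > self.z2:  # canonical unordered pair
                a, b = self.z2, self.z1
                object.__setattr__(self, "z1", a)
                object.__setattr__(self, "z2", b)

    @staticmethod
    def female(allele: int) -> "Genotype":
        return Genotype(Sex.FEMALE, allele)

    @staticmethod
    def male(a: int, b: int) -> "Genotype":
        return Genotype(Sex.MALE, min(a, b), max(a, b))

    @property
    def alleles(self) -> tuple[int, ...]:
        return (self.z1,) if self.sex == Sex.FEMALE else (self.z1, self.z2)


@dataclass
class AlleleFrequencies:
    """Frequency of the acceptance allele among female Z's, male Z's, and the
    pooled population; a sex with no individuals yields NaN."""

    p_female: float
    p_male: float

    @property
    def p_pop(self) -> float:
        return (2.0 * self.p_male + self.p_female) / 3.0


def female_accepts_nonnative(g: Genotype) -> bool:
    """A female oviposits on the non-native host iff her Z allele is ACCEPT."""
    if g.sex != Sex.FEMALE:
        raise ValueError("oviposition preference is a female phenotype")
    return g.z1 == ACCEPT


def offspring_genotype(father: Genotype, mother: Genotype, sex, rng) -> Genotype:
    """Mendelian segregation at the Z locus.

    A daughter receives one of her father's Z alleles at random (plus the W
    from her mother); a son receives one of his father's alleles at random
    plus his mother's single Z allele.
    """
    if father.sex != Sex.MALE or mother.sex != Sex.FEMALE:
        raise ValueError("offspring_genotype(father=MALE, mother=FEMALE, ...)")
    rng = np.random.default_rng(rng)
    paternal = father.z1 if rng.random() < 0.5 else father.z2
    if Sex(sex) == Sex.FEMALE:
        return Genotype.female(paternal)
    return Genotype.male(paternal, mother.z1)


def sample_male_hw(p: float, rng) -> Genotype:
    """A male genotype at Hardy-Weinberg proportions (p^2, 2p(1-p), (1-p)^2)."""
    rng = np.random.default_rng(rng)
    a = ACCEPT if rng.random() < p else REJECT
    b = ACCEPT if rng.random() < p else REJECT
    return Genotype.male(a, b)


def init_genotypes(n_females: int, p0: float, rng) -> list[tuple[Genotype, Genotype]]:
    """Founding females and their mates at allele frequency p0.

    Each female's single Z allele is ACCEPT with probability p0; her mate is
    drawn at Hardy-Weinberg proportions, which makes the pooled initial
    frequency (2 p0 + p0)/3 = p0 in expectation.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    rng = np.random.default_rng(rng)
    pairs = []
    for _ in range(n_females):
        female = Genotype.female(ACCEPT if rng.random() < p0 else REJECT)
        pairs.append((female, sample_male_hw(p0, rng)))
    return pairs


def allele_frequencies_from_arrays(female_z: np.ndarray,
                                   male_z: np.ndarray) -> AlleleFrequencies:
    """Vectorised frequency bookkeeping: female_z is (n,) of alleles, male_z
    is (m, 2) of allele pairs."""
    p_f = float(np.mean(female_z)) if len(female_z) else math.nan
    p_m = float(np.mean(male_z)) if len(male_z) else math.nan
    return AlleleFrequencies(p_female=p_f, p_male=p_m)


def population_allele_frequency(females, males) -> AlleleFrequencies:
    """Acceptance-allele frequencies of a census of Genotype collections.

    p_female is the fraction of females carrying ACCEPT; p_male is
    freq(AA) + freq(RA)/2, i.e. the mean allele dose per male Z pair; the
    pooled frequency is (2 p_male + p_female)/3.
    """
    females = list(females)
    males = list(males)
    for g in females:
        if g.sex != Sex.FEMALE:
            raise ValueError("female multiset contains a male genotype")
    for g in males:
        if g.sex != Sex.MALE:
            raise ValueError("male multiset contains a female genotype")
    female_z = np.array([g.z1 for g in females], dtype=np.float64)
    male_z = np.array([[g.z1, g.z2] for g in males], dtype=np.float64).reshape(-1, 2)
    return allele_frequencies_from_arrays(female_z, male_z)
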