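"""Synthetic data generators.

Everything needed to build a controlled experiment from scratch: a SNP panel
with transition/transversion classes, structured population allele
frequencies under the Balding-Nichols model, admixed diploid genotypes, and
low-coverage sequencing observations that can be passed through a
post-mortem deamination model emulating different library-preparation
protocols.

All generators take an explicit ``seed`` and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

BASES = np.array(["A", "C", "G", "T"])


def base_codes(values) -> np.ndarray:
    """Map a base column (categorical or string-like) to int8 codes in the
    fixed A/C/G/T order."""
    if isinstance(getattr(values, "dtype", None), pd.CategoricalDtype):
        cats = list(values.cat.categories)
        if cats == list(BASES):
            return values.cat.codes.to_numpy().astype(np.int8)
        remap = np.searchsorted(BASES, np.asarray(cats, dtype="U1")).astype(np.int8)
        return remap[values.cat.codes.to_numpy()]
    arr = np.asarray(values, dtype="U1")
    return np.searchsorted(BASES, arr).astype(np.int8)


def codes_to_bases(codes: np.ndarray) -> pd.Categorical:
    return pd.Categorical.from_codes(np.asarray(codes, dtype=np.int8),
                                     categories=list(BASES))

# (ref, alt) ordered pairs; a transition swaps within a purine or pyrimidine
# class, a transversion swaps across.
TRANSITION_PAIRS = [("C", "T"), ("T", "C"), ("A", "G"), ("G", "A")]
TRANSVERSION_PAIRS = [
    ("A", "C"), ("C", "A"), ("A", "T"), ("T", "A"),
    ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G"),
]
# Orientation restricted so that the reference (ancestral) allele carries the
# deamination-susceptible base; used for polarized panels.
TRANSITION_PAIRS_POLARIZED = [("C", "T"), ("G", "A")]

_TRANSITION_SETS = {frozenset(("C", "T")), frozenset(("A", "G"))}


def _is_transition(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    pair = np.char.add(ref.astype("U1"), alt.astype("U1"))
    return np.isin(pair, ["CT", "TC", "AG", "GA"])


@dataclass
class SNPPanel:
    """A biallelic SNP panel.

    Arrays are parallel, one entry per SNP.  Positions are 1-based and must
    be strictly increasing within a chromosome.
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype="U1")
        self.alt = np.asarray(self.alt, dtype="U1")
        n = len(self.snp_id)
        for name in ("chromosome", "position", "ref", "alt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"panel field {name!r} has inconsistent length")
        if np.any(self.ref == self.alt):
            raise ValueError("ref and alt alleles must differ at every SNP")
        for chrom in np.unique(self.chromosome):
            pos = self.position[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def is_transition(self) -> np.ndarray:
        """Boolean mask: True where the allele pair is {C,T} or {A,G}."""
        return _is_transition(self.ref, self.alt)

    @property
    def is_transversion(self) -> np.ndarray:
        return ~self.is_transition

    def subset(self, index: np.ndarray) -> "SNPPanel":
        index = np.asarray(index)
        return SNPPanel(
            snp_id=self.snp_id[index],
            chromosome=self.chromosome[index],
            position=self.position[index],
            ref=self.ref[index],
            alt=self.alt[index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chromosome": self.chromosome,
                "position": self.position,
                "ref": self.ref,
                "alt": self.alt,
                "class": np.where(self.is_transition, "transition", "transversion"),
            }
        )


@dataclass
class PopulationModel:
    """Allele frequencies for K source populations drifted from a shared
    ancestral frequency under the Balding-Nichols model."""

    panel: SNPPanel
    n_pops: int
    ancestral_freqs: np.ndarray
    fst_per_pop: np.ndarray
    pop_freqs: np.ndarray  # K x M

    def __post_init__(self) -> None:
        self.ancestral_freqs = np.asarray(self.ancestral_freqs, dtype=float)
        self.fst_per_pop = np.asarray(self.fst_per_pop, dtype=float)
        self.pop_freqs = np.asarray(self.pop_freqs, dtype=float)
        if self.pop_freqs.shape != (self.n_pops, len(self.panel)):
            raise ValueError("pop_freqs shape inconsistent with panel / n_pops")
        if np.any(self.pop_freqs < 0) or np.any(self.pop_freqs > 1):
            raise ValueError("population frequencies must lie in [0, 1]")


@dataclass
class DamageModel:
    """Terminal deamination model.

    The flip probability decays geometrically with the 1-based distance from
    the relevant fragment end: ``d_max * decay**(dist - 1)``.  In
    ``double_strand`` mode C>T applies from the 5' end and G>A from the 3'
    end; in ``single_strand`` mode C>T applies from both ends and G>A not at
    all.  With ``udg_half`` the probability is zero whenever the base sits
    more than 2 bp from both fragment ends.
    """

    d_max5: float = 0.3
    d_max3: float = 0.3
    decay: float = 0.7
    mode: str = "double_strand"
    udg_half: bool = False

    def __post_init__(self) -> None:
        for name in ("d_max5", "d_max3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must lie in (0, 1)")
        if self.mode not in ("double_strand", "single_strand"):
            raise ValueError(f"unknown damage mode {self.mode!r}")

    def rate5(self, dist5: np.ndarray) -> np.ndarray:
        return self.d_max5 * self.decay ** (np.asarray(dist5) - 1)

    def rate3(self, dist3: np.ndarray) -> np.ndarray:
        return self.d_max3 * self.decay ** (np.asarray(dist3) - 1)


OBS_COLUMNS = ["snp_index", "sample_id", "base", "base_quality",
               "fragment_length", "dist5", "dist3"]


@dataclass
class ObservationSet:
    """Per-SNP sequenced base observations.

    Thin wrapper around a DataFrame with columns ``snp_index``, ``sample_id``,
    ``base``, ``base_quality``, ``fragment_length``, ``dist5``, ``dist3``.
    Distances are 1-based from each fragment end, so
    ``dist5 + dist3 == fragment_length + 1``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in OBS_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"observation frame missing columns {missing}")
        f = self.frame
        if len(f) and not np.array_equal(
            np.asarray(f["dist5"]) + np.asarray(f["dist3"]),
            np.asarray(f["fragment_length"]) + 1,
        ):
            raise ValueError("dist5 + dist3 must equal fragment_length + 1")
        if len(f) and np.any(np.asarray(f["base_quality"]) < 0):
            raise ValueError("base qualities must be non-negative")

    def __len__(self) -> int:
        return len(self.frame)

    def with_frame(self, frame: pd.DataFrame) -> "ObservationSet":
        return ObservationSet(frame.reset_index(drop=True))


def simulate_panel(
    n_snps: int,
    transition_fraction: float = 0.8,
    seed: int | None = None,
    chromosome: int = 1,
    polarize_transitions: bool = False,
) -> SNPPanel:
    """Draw a synthetic SNP panel.

    Each SNP is independently classed as a transition with probability
    ``transition_fraction`` and assigned an allele pair uniformly within its
    class.  With ``polarize_transitions`` the reference (ancestral) allele of
    every transition SNP is the deamination-source base (C or G), emulating
    panels where the derived allele at transition sites is the deamination
    product.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not 0.0 <= transition_fraction <= 1.0:
        raise ValueError("transition_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    is_ts = rng.random(n_snps) < transition_fraction

    ts_pairs = TRANSITION_PAIRS_POLARIZED if polarize_transitions else TRANSITION_PAIRS
    ts_pairs = np.array(ts_pairs)
    tv_pairs = np.array(TRANSVERSION_PAIRS)
    ref = np.empty(n_snps, dtype="U1")
    alt = np.empty(n_snps, dtype="U1")
    k_ts = rng.integers(0, len(ts_pairs), n_snps)
    k_tv = rng.integers(0, len(tv_pairs), n_snps)
    ref[is_ts] = ts_pairs[k_ts[is_ts], 0]
    alt[is_ts] = ts_pairs[k_ts[is_ts], 1]
    ref[~is_ts] = tv_pairs[k_tv[~is_ts], 0]
    alt[~is_ts] = tv_pairs[k_tv[~is_ts], 1]

    position = np.cumsum(rng.integers(1, 2000, n_snps))
    snp_id = np.array([f"snp_{i + 1}" for i in range(n_snps)], dtype=object)
    return SNPPanel(
        snp_id=snp_id,
        chromosome=np.full(n_snps, chromosome),
        position=position,
        ref=ref,
        alt=alt,
    )


def simulate_frequencies(
    panel: SNPPanel,
    n_pops: int,
    fst_per_pop: Sequence[float],
    seed: int | None = None,
    ancestral_range: tuple[float, float] = (0.05, 0.95),
) -> PopulationModel:
    """Balding-Nichols population frequencies.

    Ancestral frequencies are uniform on ``ancestral_range``; population k
    draws ``Beta(p (1-F)/F, (1-p)(1-F)/F)`` per SNP with F its drift
    parameter.
    """
    fst = np.asarray(fst_per_pop, dtype=float)
    if fst.shape != (n_pops,):
        raise ValueError("fst_per_pop must have one entry per population")
    if np.any(fst <= 0.0) or np.any(fst >= 1.0):
        raise ValueError("each Fst must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    m = len(panel)
    p = rng.uniform(ancestral_range[0], ancestral_range[1], m)
    pop_freqs = np.empty((n_pops, m))
    for k in range(n_pops):
        ratio = (1.0 - fst[k]) / fst[k]
        pop_freqs[k] = rng.beta(p * ratio, (1.0 - p) * ratio)
    return PopulationModel(
        panel=panel,
        n_pops=n_pops,
        ancestral_freqs=p,
        fst_per_pop=fst,
        pop_freqs=pop_freqs,
    )


def simulate_genotypes(
    model: PopulationModel,
    Q: np.ndarray,
    seed: int | None = None,
    sample_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Draw diploid genotypes ``n_ij ~ Binomial(2, p_ij)`` with
    ``p_ij = sum_k q_ik f_kj``."""
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if Q.shape[1] != model.n_pops:
        raise ValueError("Q must have one column per population")
    if np.any(np.abs(Q.sum(axis=1) - 1.0) > 1e-8) or np.any(Q < 0):
        raise ValueError("each row of Q must lie on the probability simplex")
    rng = np.random.default_rng(seed)
    p = Q @ model.pop_freqs
    counts = rng.binomial(2, p).astype(np.int8)
    n = Q.shape[0]
    if sample_ids is None:
        sample_ids = [f"ind_{i + 1}" for i in range(n)]
    return GenotypeMatrix(
        samples=list(sample_ids),
        panel=model.panel,
        counts=counts,
        ploidy=np.array(["diploid"] * n, dtype=object),
    )


def simulate_observations(
    genotypes: GenotypeMatrix,
    panel: SNPPanel,
    coverage: float,
    fragment_length_mean: float = 65.0,
    seed: int | None = None,
    min_fragment_length: int = 35,
    bq_high: int = 37,
    bq_low: int = 25,
    p_bq_high: float = 0.9,
) -> ObservationSet:
    """Emulate aligned-read pileups at panel sites.

    Depth per (sample, SNP) is Poisson(``coverage``); each observation carries
    one of the two chromosomes chosen uniformly, a shifted-geometric fragment
    length with the given mean (minimum ``min_fragment_length``), a uniform
    SNP position within the fragment, and a two-point base-quality mix.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if fragment_length_mean < min_fragment_length:
        raise ValueError("fragment_length_mean must be >= min_fragment_length")
    rng = np.random.default_rng(seed)
    n, m = genotypes.counts.shape
    if m != len(panel):
        raise ValueError("genotype matrix and panel dimensions disagree")
    depth = rng.poisson(coverage, size=(n, m))
    flat = depth.ravel()
    cell = np.repeat(np.arange(n * m), flat)
    sample_idx = cell // m
    snp_idx = (cell % m).astype(np.int64)
    total = len(cell)

    g = genotypes.counts[sample_idx, snp_idx].astype(float)
    g = np.where(g < 0, np.nan, g)  # missing genotypes yield no valid draw
    carries_alt = rng.random(total) < g / 2.0
    ref_codes = np.searchsorted(BASES, panel.ref).astype(np.int8)
    alt_codes = np.searchsorted(BASES, panel.alt).astype(np.int8)
    base = np.where(carries_alt, alt_codes[snp_idx], ref_codes[snp_idx])

    # shifted geometric: L = min - 1 + Geom(p), support >= min, mean as given
    p_geom = 1.0 / (fragment_length_mean - min_fragment_length + 1.0)
    fraglen = min_fragment_length - 1 + rng.geometric(p_geom, total)
    dist5 = rng.integers(1, fraglen + 1)
    dist3 = fraglen + 1 - dist5
    bq = np.where(rng.random(total) < p_bq_high, bq_high, bq_low)

    frame = pd.DataFrame(
        {
            "snp_index": snp_idx.astype(np.int64),
            "sample_id": pd.Categorical.from_codes(
                sample_idx, categories=[str(s) for s in genotypes.samples]
            ),
            "base": codes_to_bases(base),
            "base_quality": bq.astype(np.int16),
            "fragment_length": fraglen.astype(np.int64),
            "dist5": dist5.astype(np.int64),
            "dist3": dist3.astype(np.int64),
        },
        copy=False,
    )
    return ObservationSet(frame)


def apply_damage(
    obs: ObservationSet,
    panel: SNPPanel,
    dm: DamageModel,
    seed: int | None = None,
) -> ObservationSet:
    """Apply terminal deamination to an observation set.

    Only source bases C and G can change (C>T, G>A); the flip probability
    follows the damage model's geometric decay from the fragment ends.  The
    flipped base may fall outside the SNP's allele pair; such observations
    are representable here and discarded later at calling.
    """
    rng = np.random.default_rng(seed)
    f = obs.frame
    codes = base_codes(f["base"]).copy()
    dist5 = np.asarray(f["dist5"])
    dist3 = np.asarray(f["dist3"])

    r5 = dm.rate5(dist5)
    r3 = dm.rate3(dist3)
    if dm.mode == "double_strand":
        p_ct = r5
        p_ga = r3
    else:  # single_strand: C>T accrues from both ends, no G>A
        p_ct = 1.0 - (1.0 - r5) * (1.0 - r3)
        p_ga = np.zeros_like(r3)
    if dm.udg_half:
        interior = np.minimum(dist5, dist3) > 2
        p_ct = np.where(interior, 0.0, p_ct)
        p_ga = np.where(interior, 0.0, p_ga)

    u = rng.random(len(codes))
    is_c = codes == 1
    is_g = codes == 2
    codes[is_c & (u < p_ct)] = 3  # C -> T
    codes[is_g & (u < p_ga)] = 0  # G -> A

    new = f.copy()
    new["base"] = codes_to_bases(codes)
    return obs.with_frame(new)
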