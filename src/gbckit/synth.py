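"""Synthetic reference breeds and crossbred genotypes.

Reference allele frequencies follow the Balding–Nichols construction:
an ancestral frequency p0 per SNP is drawn uniformly, and each breed's
frequency is Beta(p0 (1-F)/F, (1-p0) (1-F)/F) around it. The single
differentiation parameter F plays the role of an Fst: small F keeps
breeds close to the shared ancestor (high between-breed frequency
correlation), large F lets them drift apart. Crossbred genotypes are
drawn either independently per locus as Binomial(2, sum_j w_j x_ij)
under HWE, or as two gamete mosaics whose breed-of-origin is constant
within ancestry blocks.

Three named scenarios mirror the composite-cattle settings the
estimators were designed around: a Brangus-like two-breed cross with
distant ancestors, a Beefmaster-like three-breed cross with one
correlated ancestor pair, and a two-generation Ultrablack-like
backcross.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AlleleFrequencyTable, GenotypeMatrix, SNPMap

__all__ = [
    "BreedSimConfig",
    "CrossSimConfig",
    "Scenario",
    "simulate_breed_frequencies",
    "simulate_crossbreds",
    "uniform_snp_map",
    "make_scenarios",
]

# substream tags so each operation is independently reproducible from one seed
_STREAM_FREQ = 1
_STREAM_CROSS = 2
_STREAM_SCENARIO = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class BreedSimConfig:
    M: int = 5000
    K: int = 2
    F: float = 0.25
    ancestral_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0
    breed_names: list[str] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.F < 1.0):
            raise ValueError("differentiation F must lie in (0, 1)")
        low, high = self.ancestral_range
        if not (0.0 < low < high < 1.0):
            raise ValueError("ancestral range must satisfy 0 < low < high < 1")
        if self.M < 1 or self.K < 1:
            raise ValueError("M and K must be positive")


@dataclass
class CrossSimConfig:
    W: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    n: int = 100
    mode: str = "hwe"
    block_length: int = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if (self.W < 0).any() or abs(self.W.sum() - 1.0) > 1e-8:
            raise ValueError("W must be a probability simplex")
        if self.n < 1:
            raise ValueError("need at least one animal")
        if self.mode not in ("hwe", "block"):
            raise ValueError(f"unknown mode {self.mode!r}")


def simulate_breed_frequencies(cfg: BreedSimConfig) -> AlleleFrequencyTable:
    """Balding–Nichols breed frequencies around a shared ancestor."""
    rng = _rng(cfg.seed, _STREAM_FREQ)
    low, high = cfg.ancestral_range
    p0 = rng.uniform(low, high, size=cfg.M)
    ratio = (1.0 - cfg.F) / cfg.F
    freq = rng.beta(
        p0[:, None] * ratio, (1.0 - p0)[:, None] * ratio, size=(cfg.M, cfg.K)
    )
    freq = np.clip(freq, 1e-6, 1.0 - 1e-6)
    names = cfg.breed_names or [f"breed{k + 1}" for k in range(cfg.K)]
    snp_ids = [f"snp{i + 1}" for i in range(cfg.M)]
    return AlleleFrequencyTable(snp_ids, names, freq)


def uniform_snp_map(
    M: int, n_chrom: int = 10, chrom_length: int = 100_000_000, seed: int = 0
) -> SNPMap:
    """Evenly spaced map: M SNPs split across n_chrom chromosomes."""
    per = np.full(n_chrom, M // n_chrom)
    per[: M % n_chrom] += 1
    rows = []
    i = 0
    for c in range(n_chrom):
        if per[c] == 0:
            continue
        positions = np.linspace(1, chrom_length, per[c], dtype=np.int64)
        for p in positions:
            i += 1
            rows.append({"snp_id": f"snp{i}", "chrom": f"{c + 1:02d}", "pos": int(p)})
    return SNPMap(pd.DataFrame(rows))


def simulate_crossbreds(
    F: AlleleFrequencyTable, cfg: CrossSimConfig, snp_map: SNPMap | None = None
) -> GenotypeMatrix:
    """Crossbred genotypes with admixture proportions cfg.W.

    hwe mode: dosage ~ Binomial(2, sum_j w_j x_ij), independent per
    locus. block mode: each of the two gametes is an ancestry mosaic —
    breed-of-origin drawn from W per block of ``block_length`` bp — and
    each allele is Bernoulli in the originating breed's frequency.
    """
    if cfg.W.shape != (F.n_breeds,):
        raise ValueError("W length must match breed count")
    rng = _rng(cfg.seed, _STREAM_CROSS)
    animal_ids = [f"x{a + 1}" for a in range(cfg.n)]
    if cfg.mode == "hwe":
        f = np.clip(F.freq @ cfg.W, 0.0, 1.0)
        dosage = rng.binomial(2, f[None, :], size=(cfg.n, F.n_snps)).astype(float)
    else:
        if snp_map is None:
            raise ValueError("block mode requires a SNP map")
        order = pd.Index(snp_map.table["snp_id"]).get_indexer(F.snp_ids)
        if (order < 0).any():
            raise ValueError("SNP map does not cover all frequency-table SNPs")
        block_of = _block_index(snp_map, F.snp_ids, cfg.block_length)
        n_blocks = block_of.max() + 1
        dosage = np.zeros((cfg.n, F.n_snps))
        for _gamete in range(2):
            origin = rng.choice(F.n_breeds, size=(cfg.n, n_blocks), p=cfg.W)
            per_snp_origin = origin[:, block_of]  # animals x snps breed index
            p = F.freq[np.arange(F.n_snps)[None, :], per_snp_origin]
            dosage += rng.random((cfg.n, F.n_snps)) < p
    mask = np.zeros_like(dosage, dtype=bool)
    return GenotypeMatrix(animal_ids, F.snp_ids, dosage, mask)


def _block_index(snp_map: SNPMap, snp_ids: list[str], block_length: int) -> np.ndarray:
    t = snp_map.table.set_index("snp_id").loc[snp_ids]
    chrom_codes = pd.factorize(t["chrom"])[0]
    within = (t["pos"].to_numpy() - 1) // block_length
    key = pd.MultiIndex.from_arrays([chrom_codes, within])
    return pd.factorize(key)[0]


@dataclass
class Scenario:
    name: str
    frequencies: AlleleFrequencyTable
    genotypes: GenotypeMatrix
    true_W: np.ndarray | None
    snp_map: SNPMap
    description: str = ""


def _independent_breeds(
    M: int, names: list[str], Fs: list[float], seed: int, sub: int
) -> AlleleFrequencyTable:
    """One breed per independent ancestral draw (between-breed r ~ 0)."""
    cols = []
    for k, (name, Fk) in enumerate(zip(names, Fs)):
        t = simulate_breed_frequencies(
            BreedSimConfig(M=M, K=1, F=Fk, seed=seed * 1000 + sub * 100 + k,
                           breed_names=[name])
        )
        cols.append(t.freq[:, 0])
    snp_ids = [f"snp{i + 1}" for i in range(M)]
    return AlleleFrequencyTable(snp_ids, names, np.column_stack(cols))


def _correlated_pair(
    M: int, names: list[str], seed: int, sub: int,
    F_intermediate: float = 0.02, F_pair: float = 0.45,
) -> np.ndarray:
    """Two breeds drawn around a shared intermediate ancestor; the
    moment calculation for Balding–Nichols targets a between-breed
    Pearson correlation near 0.4 at these defaults."""
    rng = _rng(seed * 1000 + sub, _STREAM_SCENARIO)
    p0 = rng.uniform(0.1, 0.9, size=M)
    ratio_q = (1.0 - F_intermediate) / F_intermediate
    q = rng.beta(p0 * ratio_q, (1.0 - p0) * ratio_q)
    ratio_b = (1.0 - F_pair) / F_pair
    pair = rng.beta(q[:, None] * ratio_b, (1.0 - q)[:, None] * ratio_b, size=(M, 2))
    return np.clip(pair, 1e-6, 1.0 - 1e-6)


def make_scenarios(
    seed: int = 1, M: int = 5000, n: int = 100
) -> dict[str, Scenario]:
    """Three seeded composite-breed fixtures.

    brangus_like: two distant breeds (independent ancestors, r < 0.15),
    W = (0.625, 0.375). beefmaster_like: three breeds, W = (0.5, 0.25,
    0.25), with the second and third breeds correlated (r ~ 0.4).
    ultrablack_like: a stabilized 0.625/0.375 composite backcrossed
    50/50 to breed 1, giving expected ancestry (0.8125, 0.1875).
    """
    snp_map = uniform_snp_map(M)
    out: dict[str, Scenario] = {}

    # Brangus-like: two remotely related ancestors
    Fb = _independent_breeds(M, ["angus", "brahman"], [0.25, 0.25], seed, sub=1)
    Wb = np.array([0.625, 0.375])
    Gb = simulate_crossbreds(Fb, CrossSimConfig(W=Wb, n=n, seed=seed * 1000 + 11))
    out["brangus_like"] = Scenario(
        "brangus_like", Fb, Gb, Wb, snp_map,
        "two distant reference breeds, composite at 5/8 : 3/8",
    )

    # Beefmaster-like: breed 1 independent; breeds 2 and 3 share an
    # intermediate ancestor so their frequencies correlate around 0.4
    pair = _correlated_pair(M, ["hereford", "shorthorn"], seed, sub=2)
    solo = _independent_breeds(M, ["brahman"], [0.25], seed, sub=3)
    freq = np.column_stack([solo.freq[:, 0], pair])
    Ff = AlleleFrequencyTable(
        [f"snp{i + 1}" for i in range(M)], ["brahman", "hereford", "shorthorn"], freq
    )
    Wf = np.array([0.5, 0.25, 0.25])
    Gf = simulate_crossbreds(Ff, CrossSimConfig(W=Wf, n=n, seed=seed * 1000 + 12))
    out["beefmaster_like"] = Scenario(
        "beefmaster_like", Ff, Gf, Wf, snp_map,
        "three reference breeds with one correlated pair (r ~ 0.4)",
    )

    # Ultrablack-like: gamete from the stabilized composite + gamete from
    # breed 1, so expected ancestry is 0.5*(0.625, 0.375) + (0.5, 0)
    rng = _rng(seed * 1000 + 13, _STREAM_SCENARIO)
    f_comp = Fb.freq @ Wb
    gam_comp = (rng.random((n, M)) < f_comp[None, :]).astype(float)
    gam_a = (rng.random((n, M)) < Fb.freq[:, 0][None, :]).astype(float)
    dosage = gam_comp + gam_a
    Gu = GenotypeMatrix(
        [f"ub{a + 1}" for a in range(n)], Fb.snp_ids, dosage,
        np.zeros_like(dosage, dtype=bool),
    )
    out["ultrablack_like"] = Scenario(
        "ultrablack_like", Fb, Gu, np.array([0.8125, 0.1875]), snp_map,
        "composite backcrossed 50/50 to breed 1 (expected 81.25/18.75)",
    )
    return out
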