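"""Synthetic Pool-Seq datasets with known divergence structure.

The generator emulates the statistical structure the divergence scan assumes:

* eleven pools of pooled diploids genotyped at ploidy C = 20 (frequencies on a
  1/20 grid), grouped into three superpools (6 + 3 + 2 pools) with replicate
  pools inside the superpools, Poisson read depths in the 60–98 range;
* a shared ancestral allele-frequency spectrum (truncated Beta, keeping
  frequencies off the fixation boundary so the 0.05-grid quantization rarely
  fixes a SNP);
* Balding–Nichols population divergence around the ancestral frequency:
  each population's frequency is a draw from
  Beta(p(1−F)/F, (1−p)(1−F)/F), whose mean is p and variance F·p(1−p);
* localized islands of elevated divergence, injected by raising the
  Balding–Nichols parameter of one designated population inside each island
  interval;
* a ground-truth record (per-SNP ancestral and population frequencies, island
  membership) for recovery benchmarks.

Calibration
-----------
``background_fst`` and the per-island ``fst`` are expressed on the scale the
scan actually reports: the expected pairwise Nei F_ST the Pool-Seq estimator
measures between the two compared superpools.  That estimator is inflated by
binomial(C) pool sampling, so the generator converts the dial F into a
per-population Balding–Nichols parameter in closed form
(:func:`calibrate_bn_divergence`); without the correction a nominal
background of 0.02 would be reported as ≈0.025 by the scan and island calling
against absolute thresholds would be misleading.  Dials at or below the
sampling-noise floor τ/(4−τ) map to zero true divergence.

The generator deliberately omits read-level error, linkage disequilibrium and
haplotype structure: SNPs are independent given the ancestral spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .pool_io import MISSING, PoolAlleleMatrix, PoolInfo, ContractError

DEFAULT_PLOIDY = 20


@dataclass(frozen=True)
class PoolSpec:
    pool_id: str
    population: str
    ploidy: int = DEFAULT_PLOIDY
    mean_depth: float = 70.0


@dataclass(frozen=True)
class IslandSpec:
    """A region of elevated divergence in one population."""

    lg: str
    start: int
    end: int
    fst: float
    diverged_population: str = "AI"


@dataclass(frozen=True)
class ReplicateGroup:
    """Pools sharing population frequencies; perturb_fst > 0 redraws each
    member's frequencies around the shared ones (temporal-replicate style),
    perturb_fst = 0 shares them exactly (same-individuals style)."""

    pool_ids: tuple[str, ...]
    perturb_fst: float = 0.0


@dataclass
class SimConfig:
    """Generator configuration; the defaults are the study-like conditions."""

    seed: int
    lg_lengths: dict[str, int] = field(
        default_factory=lambda: {f"LG{i:02d}": 2_000_000 for i in range(1, 6)}
    )
    snp_density: float = 1e-3
    pools: list[PoolSpec] = field(default_factory=lambda: list(DEFAULT_POOLS))
    superpool_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SUPERPOOLS)
    )
    background_fst: float = 0.02
    islands: list[IslandSpec] = field(default_factory=list)
    ancestral_freq_beta: tuple[float, float] = (0.7, 0.7)
    freq_clip: tuple[float, float] = (0.05, 0.95)
    replicate_groups: list[ReplicateGroup] = field(
        default_factory=lambda: list(DEFAULT_REPLICATES)
    )
    comparison: tuple[str, str] = ("EBS", "AI")
    missing_fraction: float = 0.002

    def validate(self) -> None:
        if not (0 <= self.background_fst < 1):
            raise ContractError("background_fst must be in [0, 1)")
        pool_ids = [p.pool_id for p in self.pools]
        if len(set(pool_ids)) != len(pool_ids):
            raise ContractError("duplicate pool ids")
        missing = [p for p in pool_ids if p not in self.superpool_map]
        if missing:
            raise ContractError(f"pools without superpool assignment: {missing}")
        populations = {p.population for p in self.pools}
        by_lg: dict[str, list[IslandSpec]] = {}
        for isl in self.islands:
            if isl.lg not in self.lg_lengths:
                raise ContractError(f"island on unknown linkage group {isl.lg}")
            if not (1 <= isl.start < isl.end <= self.lg_lengths[isl.lg]):
                raise ContractError(f"island {isl} outside its linkage group")
            if isl.fst <= self.background_fst:
                raise ContractError("island fst must exceed background_fst")
            if isl.diverged_population not in populations:
                raise ContractError(
                    f"island diverged population {isl.diverged_population!r} unknown"
                )
            by_lg.setdefault(isl.lg, []).append(isl)
        for lg, isls in by_lg.items():
            isls = sorted(isls, key=lambda i: i.start)
            for a, b in zip(isls, isls[1:]):
                if b.start <= a.end:
                    raise ContractError(f"overlapping islands on {lg}")
        for grp in self.replicate_groups:
            for pid in grp.pool_ids:
                if pid not in pool_ids:
                    raise ContractError(f"replicate group names unknown pool {pid}")


# The eleven-pool roster: pool ids, superpool regions and mean read depths
# follow the study design the generator emulates (6 + 3 + 2 pools, depths
# 60-98 pre-filtering).
DEFAULT_POOLS = (
    PoolSpec("perv_a", "EBS", mean_depth=98),
    PoolSpec("perv_b", "EBS", mean_depth=88),
    PoolSpec("zhemchug", "EBS", mean_depth=71),
    PoolSpec("pribilof", "EBS", mean_depth=84),
    PoolSpec("kodiak_2003", "EBS", mean_depth=70),
    PoolSpec("kodiak_2005", "EBS", mean_depth=79),
    PoolSpec("near", "AI", mean_depth=60),
    PoolSpec("kiska", "AI", mean_depth=60),
    PoolSpec("adak", "AI", mean_depth=71),
    PoolSpec("wash_a", "WA", mean_depth=87),
    PoolSpec("wash_b", "WA", mean_depth=81),
)
DEFAULT_SUPERPOOLS = {p.pool_id: p.population for p in DEFAULT_POOLS}
DEFAULT_REPLICATES = (
    ReplicateGroup(("wash_a", "wash_b"), perturb_fst=0.0),
    ReplicateGroup(("perv_a", "perv_b"), perturb_fst=0.0),
    ReplicateGroup(("kodiak_2003", "kodiak_2005"), perturb_fst=0.002),
)


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset: per-SNP frequencies and islands."""

    snps: pd.DataFrame  # snp_id, lg, pos, ancestral_p, pop_<id>..., island_id
    islands: pd.DataFrame  # island_id, lg, start, end, fst, diverged_population

    def write(self, path) -> None:
        self.snps.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def draw_population_freq(ancestral_p, F, rng) -> np.ndarray | float:
    """Balding–Nichols draw: Beta(p(1−F)/F, (1−p)(1−F)/F); p itself when F=0.

    Mean is p and variance F·p(1−p), so F parameterizes the divergence of the
    population from the common ancestor.
    """
    p = np.asarray(ancestral_p, dtype=float)
    F = np.asarray(F, dtype=float)
    if np.any((F < 0) | (F >= 1)):
        raise ContractError("divergence parameter F must be in [0, 1)")
    if np.any((p <= 0) | (p >= 1)):
        raise ContractError("ancestral frequency must be in (0, 1)")
    Fb = np.broadcast_to(F, p.shape) if p.ndim else F
    if p.ndim == 0:
        if float(Fb) == 0.0:
            return float(p)
        scale = (1.0 - float(Fb)) / float(Fb)
        return float(rng.beta(float(p) * scale, (1.0 - float(p)) * scale))
    out = p.copy()
    nz = Fb > 0
    if np.any(nz):
        scale = (1.0 - Fb[nz]) / Fb[nz]
        out[nz] = rng.beta(p[nz] * scale, (1.0 - p[nz]) * scale)
    return out


def sample_pool_counts(pop_freq, C, rng) -> np.ndarray | int:
    """Binomial(C, pop_freq) reference-allele counts on the 1/C ploidy grid."""
    p = np.asarray(pop_freq, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ContractError("population frequency must be in [0, 1]")
    if C < 1:
        raise ContractError("ploidy must be >= 1")
    out = rng.binomial(C, p)
    return int(out) if np.asarray(pop_freq).ndim == 0 else out


def calibrate_bn_divergence(
    target_fst: float, ploidy: int, k_x: int, k_y: int
) -> float:
    """Per-population Balding–Nichols parameter for a target measured F_ST.

    The Nei estimator applied to superpool mean frequencies has expectation
    ≈ N/(4−N) with N = 2c + (1−c)τ, where c is the per-population divergence
    and τ = 1/(C·k_X) + 1/(C·k_Y) is the binomial pool-sampling variance
    contribution of the two superpools (k pools each at ploidy C).  Solving
    N = 4F/(1+F) for c gives the parameter whose measured pairwise F_ST is F.
    Targets at or below the sampling floor τ/(4−τ) return 0 (no divergence
    can be removed from the estimator).
    """
    if not (0 <= target_fst < 1):
        raise ContractError("target F_ST must be in [0, 1)")
    tau = 1.0 / (ploidy * k_x) + 1.0 / (ploidy * k_y)
    N = 4.0 * target_fst / (1.0 + target_fst)
    return max((N - tau) / (2.0 - tau), 0.0)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> tuple[PoolAlleleMatrix, TruthTable]:
    """Simulate a pooled allele-count dataset plus its ground truth.

    Deterministic for a fixed ``config.seed``.  Within each linkage group the
    SNP count is Poisson(length × density) and positions are a sorted uniform
    draw without replacement.  Population frequencies are Balding–Nichols
    draws at the calibrated background parameter, with the designated diverged
    population redrawn at the calibrated island parameter inside island
    intervals.  Pools sample Binomial(C) allele counts from their population's
    (possibly replicate-perturbed) frequencies, and per-SNP per-pool depths
    are Poisson(mean_depth), with a small configured fraction of SNPs given
    depth 0 in one pool to exercise the missing-data filter.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    populations = sorted({p.population for p in config.pools})

    sp_members: dict[str, int] = {}
    for pid, sp in config.superpool_map.items():
        sp_members[sp] = sp_members.get(sp, 0) + 1
    k_x = sp_members[config.comparison[0]]
    k_y = sp_members[config.comparison[1]]
    ploidy = config.pools[0].ploidy
    c_bg = calibrate_bn_divergence(config.background_fst, ploidy, k_x, k_y)

    lg_frames = []
    truth_frames = []
    count_blocks = []
    depth_blocks = []
    a, b = config.ancestral_freq_beta
    lo, hi = config.freq_clip

    pool_to_group = {}
    for grp in config.replicate_groups:
        for pid in grp.pool_ids:
            pool_to_group[pid] = grp

    for lg, length in config.lg_lengths.items():
        n = rng.poisson(length * config.snp_density)
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n, replace=False))
        anc = np.clip(rng.beta(a, b, size=n), lo, hi)

        # per-SNP Balding-Nichols parameter per population
        F_pop = {pop: np.full(n, c_bg) for pop in populations}
        island_id = np.full(n, ".", dtype=object)
        for isl in config.islands:
            if isl.lg != lg:
                continue
            inside = (pos >= isl.start) & (pos <= isl.end)
            # island parameter: raise the diverged population so the summed
            # between-population divergence matches the calibrated target
            c_isl = max(
                2.0 * calibrate_bn_divergence(isl.fst, ploidy, k_x, k_y) - c_bg,
                c_bg,
            )
            F_pop[isl.diverged_population][inside] = c_isl
            tag = f"{isl.lg}:{isl.start}-{isl.end}"
            island_id[inside] = tag

        pop_freq = {
            pop: np.asarray(draw_population_freq(anc, F_pop[pop], rng))
            for pop in populations
        }

        counts = np.empty((n, len(config.pools)), dtype=np.int64)
        depths = np.empty((n, len(config.pools)), dtype=np.int64)
        group_freq_cache: dict[tuple[int, str], np.ndarray] = {}
        for j, pool in enumerate(config.pools):
            base = pop_freq[pool.population]
            grp = pool_to_group.get(pool.pool_id)
            if grp is not None and grp.perturb_fst > 0:
                safe = np.clip(base, 1e-9, 1 - 1e-9)
                freqs = np.asarray(
                    draw_population_freq(safe, grp.perturb_fst, rng)
                )
            else:
                freqs = base
            counts[:, j] = sample_pool_counts(freqs, pool.ploidy, rng)
            depths[:, j] = rng.poisson(pool.mean_depth, size=n)

        # depth-zero dropouts to exercise the missing-data filter
        if config.missing_fraction > 0 and n > 0:
            n_drop = rng.binomial(n, config.missing_fraction)
            if n_drop:
                rows = rng.choice(n, size=n_drop, replace=False)
                cols = rng.integers(0, len(config.pools), size=n_drop)
                depths[rows, cols] = 0
                counts[rows, cols] = MISSING

        lg_frames.append(
            pd.DataFrame(
                {
                    "lg": lg,
                    "pos": pos,
                    "ref": "A",
                    "alt": "T",
                }
            )
        )
        truth = pd.DataFrame(
            {
                "snp_id": [f"{lg}:{p}" for p in pos],
                "lg": lg,
                "pos": pos,
                "ancestral_p": anc,
                "island_id": island_id,
            }
        )
        for pop in populations:
            truth[f"pop_{pop}"] = pop_freq[pop]
        truth_frames.append(truth)
        count_blocks.append(counts)
        depth_blocks.append(depths)

    snps = pd.concat(lg_frames, ignore_index=True)
    matrix = PoolAlleleMatrix(
        snps=snps,
        counts=np.vstack(count_blocks),
        pools=[
            PoolInfo(p.pool_id, p.ploidy, config.superpool_map[p.pool_id])
            for p in config.pools
        ],
        depths=np.vstack(depth_blocks),
    )
    islands_df = pd.DataFrame(
        [
            {
                "island_id": f"{i.lg}:{i.start}-{i.end}",
                "lg": i.lg,
                "start": i.start,
                "end": i.end,
                "fst": i.fst,
                "diverged_population": i.diverged_population,
            }
            for i in config.islands
        ]
    )
    return matrix, TruthTable(pd.concat(truth_frames, ignore_index=True), islands_df)


def default_island_set(fst: float = 0.15, length: int = 160_000) -> list[IslandSpec]:
    """Six well-separated island intervals across the default five-LG genome."""
    spots = [
        ("LG01", 400_000),
        ("LG02", 1_000_000),
        ("LG03", 300_000),
        ("LG03", 1_500_000),
        ("LG04", 800_000),
        ("LG05", 1_200_000),
    ]
    return [IslandSpec(lg, s, s + length, fst) for lg, s in spots]


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

def config_from_yaml(path) -> SimConfig:
    """Read a SimConfig from YAML; the seed key is mandatory."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ContractError("simulation config must specify a seed")
    kwargs = {"seed": int(raw["seed"])}
    if "lg_lengths" in raw:
        kwargs["lg_lengths"] = {str(k): int(v) for k, v in raw["lg_lengths"].items()}
    for key in ("snp_density", "background_fst", "missing_fraction"):
        if key in raw:
            kwargs[key] = float(raw[key])
    if "ancestral_freq_beta" in raw:
        kwargs["ancestral_freq_beta"] = tuple(float(x) for x in raw["ancestral_freq_beta"])
    if "freq_clip" in raw:
        kwargs["freq_clip"] = tuple(float(x) for x in raw["freq_clip"])
    if "comparison" in raw:
        kwargs["comparison"] = tuple(str(x) for x in raw["comparison"])
    if "pools" in raw:
        kwargs["pools"] = [
            PoolSpec(
                str(p["pool_id"]),
                str(p["population"]),
                int(p.get("ploidy", DEFAULT_PLOIDY)),
                float(p.get("mean_depth", 70.0)),
            )
            for p in raw["pools"]
        ]
        kwargs["superpool_map"] = {
            str(p["pool_id"]): str(p.get("superpool", p["population"]))
            for p in raw["pools"]
        }
        # custom pool rosters drop the study-roster replicate defaults
        kwargs.setdefault("replicate_groups", [])
    if "islands" in raw:
        kwargs["islands"] = [
            IslandSpec(
                str(i["lg"]), int(i["start"]), int(i["end"]), float(i["fst"]),
                str(i.get("diverged_population", "AI")),
            )
            for i in raw["islands"]
        ]
    if "replicate_groups" in raw:
        kwargs["replicate_groups"] = [
            ReplicateGroup(tuple(g["pool_ids"]), float(g.get("perturb_fst", 0.0)))
            for g in raw["replicate_groups"]
        ]
    return SimConfig(**kwargs)
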