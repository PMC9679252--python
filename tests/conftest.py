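import numpy as np
import pandas as pd
import pytest

import poolscan as ps


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_220)


@pytest.fixture(scope="session")
def island_config():
    """Study-like config with the six-island truth set."""
    return ps.SimConfig(seed=11, islands=ps.default_island_set())


@pytest.fixture(scope="session")
def island_dataset(island_config):
    return ps.simulate_dataset(island_config)


@pytest.fixture(scope="session")
def null_config():
    """Study-like config with no injected islands (pure background)."""
    return ps.SimConfig(seed=7)


@pytest.fixture(scope="session")
def null_dataset(null_config):
    return ps.simulate_dataset(null_config)


def superpool_pair(matrix, label_x, label_y):
    members = matrix.superpool_members()
    return (
        ps.SuperpoolSpec(label_x, tuple(matrix.pools[j].pool_id for j in members[label_x])),
        ps.SuperpoolSpec(label_y, tuple(matrix.pools[j].pool_id for j in members[label_y])),
    )


def run_scan(matrix, lg_lengths, label_x="EBS", label_y="AI", scheme=None):
    """Filter, compute per-SNP stats and scan windows for one comparison."""
    scheme = scheme or ps.WindowScheme()
    filtered, _ = ps.filter_depth(matrix)
    filtered = ps.filter_complete_biallelic_variant(filtered)
    sp_x, sp_y = superpool_pair(filtered, label_x, label_y)
    per_snp = ps.per_snp_stats(filtered, sp_x, sp_y)
    per_snp[f"p_{label_x}"] = per_snp["p_x"]
    per_snp[f"p_{label_y}"] = per_snp["p_y"]
    ploidies = {
        label_x: sp_x.effective_ploidy(),
        label_y: sp_y.effective_ploidy(),
    }
    windows = ps.scan_windows(per_snp, lg_lengths, scheme, superpool_ploidies=ploidies)
    return filtered, per_snp, windows


@pytest.fixture(scope="session")
def island_scan(island_dataset, island_config):
    matrix, truth = island_dataset
    filtered, per_snp, windows = run_scan(matrix, island_config.lg_lengths)
    return filtered, per_snp, windows, truth


def tiny_matrix(counts, ploidy=20, depths=None, superpools=None, lg="LG01"):
    """Build a small PoolAlleleMatrix from a (snps x pools) count array."""
    counts = np.asarray(counts)
    n_snps, n_pools = counts.shape
    snps = pd.DataFrame(
        {
            "lg": lg,
            "pos": np.arange(1, n_snps + 1) * 10,
            "ref": "A",
            "alt": "T",
        }
    )
    superpools = superpools or {}
    pools = [
        ps.PoolInfo(f"pool{j + 1}", ploidy, superpools.get(f"pool{j + 1}", ""))
        for j in range(n_pools)
    ]
    return ps.PoolAlleleMatrix(snps, counts, pools, depths=depths)
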