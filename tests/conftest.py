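"""Shared fixtures: a small synthetic cohort reused across test modules.

The cohort is generated once per session at a reduced scale (8 samples per
class, 500 cells, 1000 genes) so individual tests stay fast; tests that need
specific regimes build their own configs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from amlss import cell_states, subtype_signatures
from amlss.synthetic_data import SimulationConfig, simulate_cells, simulate_genotype_reads


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_samples_per_class=8,
        n_nbm_samples=2,
        n_cells_per_sample=500,
        n_genes=1000,
        seed=11,
    )


@pytest.fixture(scope="session")
def cohort(small_config):
    """(AnnData, truth) for the small cohort, QC'd and relabeled."""
    cells, truth = simulate_cells(small_config)
    kept, _ = cell_states.qc_filter(cells.obs)
    cells = cells[cells.obs_names.isin(kept.index)].copy()
    relabeled, _ = cell_states.relabel_aml_immature(cells.obs)
    cells.obs = relabeled
    return cells, truth


@pytest.fixture(scope="session")
def cohort_reads(cohort, small_config):
    cells, truth = cohort
    return simulate_genotype_reads(cells, truth, small_config)


@pytest.fixture(scope="session")
def cohort_signature(cohort):
    """Signature derived from the small cohort (exclusion stage on)."""
    cells, truth = cohort
    aml = cells[cells.obs["origin"] == "AML"]
    avg = cell_states.sample_celltype_averages(aml.X, list(aml.var_names), aml.obs)
    avg_log = subtype_signatures.log2_threshold_transform(avg, floor=0.01)
    linear = np.expm1(cell_states.normalize_log1p_cp10k(aml.X))
    ct_means = cell_states.average_expression_by_group(
        linear, list(aml.var_names), aml.obs["predicted_type"].to_numpy()
    )
    sc = truth.sample_class[truth.sample_class.isin(["I", "II"])]
    return subtype_signatures.derive_signature(avg_log, sc, celltype_means=ct_means)


def make_umi_calls(
    rng: np.random.Generator,
    group_sizes: dict[str, int],
    true_fraction: float,
    variant_id: str = "v1",
    het_allele_prob: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """UMI-call table drawn from the heterozygous transmission model.

    Each group gets ``group_sizes[g]`` UMIs; a UMI comes from a mutated cell
    with probability ``true_fraction`` and is then called mutated with
    probability ``het_allele_prob``. Returns (calls frame, cell->group map).
    """
    rows, groups = [], {}
    for g, n in group_sizes.items():
        for i in range(n):
            cell = f"{g}:c{i}"
            groups[cell] = g
            mutated_cell = rng.random() < true_fraction
            call = "mutated" if (mutated_cell and rng.random() < het_allele_prob) else "reference"
            rows.append(
                {
                    "cell_barcode": cell,
                    "umi": f"u{i}",
                    "variant_id": variant_id,
                    "call": call,
                    "n_mut_reads": 3 if call == "mutated" else 0,
                    "n_ref_reads": 0 if call == "mutated" else 3,
                }
            )
    return pd.DataFrame(rows), pd.Series(groups)
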