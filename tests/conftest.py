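"""Shared fixtures: small synthetic datasets and a reference annotation.

Everything is generated programmatically at test time; nothing binary is
stored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mosaicmeth import simulate
from mosaicmeth.meth_io import GeneAnnotation, MethylationCallMatrix


@pytest.fixture(scope="session")
def small_config():
    """A fast generator config: ~4000 CpGs, 5 planted DMRs, 10 SNPs."""
    return simulate.SimulationConfig(
        scaffold_length=200_000, n_genes=20, n_dmrs=5,
        dmr_effect=(0.25, 0.25), dmr_width=(5, 10),
        conversion_failure_rate=0.0, n_snps=10, seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    model, truth, matrix, _ = simulate.simulate_dataset(small_config)
    return model, truth, matrix


@pytest.fixture(scope="session")
def published_style_annotation():
    """Two genes with exon layouts consistent with the published DMR table.

    The exon boundaries are a synthetic stand-in: the real annotation is not
    distributed, so exons are laid out to be consistent with the printed
    gene spans, exon counts, strands and per-DMR exon hits (gene 1:
    scaffold02569 76,199-79,126, 8 exons, + strand; gene 2: scaffold01005
    527,546-535,133, 6 exons, - strand).
    """
    genes = pd.DataFrame(
        [
            ("Dapma7bEVm000710", "scaffold02569", 76199, 79126, "+"),
            ("Dapma7bEVm003762", "scaffold01005", 527546, 535133, "-"),
        ],
        columns=["gene_id", "scaffold", "start", "end", "strand"],
    ).set_index("gene_id")
    exons = pd.DataFrame(
        [
            # + strand gene: index 1 at lowest coordinates
            ("Dapma7bEVm000710", 1, 76199, 76600),
            ("Dapma7bEVm000710", 2, 76700, 77150),
            ("Dapma7bEVm000710", 3, 77200, 77300),
            ("Dapma7bEVm000710", 4, 77340, 77450),
            ("Dapma7bEVm000710", 5, 77500, 77650),
            ("Dapma7bEVm000710", 6, 77690, 77930),
            ("Dapma7bEVm000710", 7, 78000, 78500),
            ("Dapma7bEVm000710", 8, 78600, 79126),
            # - strand gene: index 1 at highest coordinates
            ("Dapma7bEVm003762", 1, 534900, 535133),
            ("Dapma7bEVm003762", 2, 534700, 534880),
            ("Dapma7bEVm003762", 3, 534300, 534600),
            ("Dapma7bEVm003762", 4, 534050, 534250),
            ("Dapma7bEVm003762", 5, 533500, 533900),
            ("Dapma7bEVm003762", 6, 527546, 533000),
        ],
        columns=["gene_id", "exon_index", "start", "end"],
    )
    return GeneAnnotation(genes, exons)


def tiny_matrix(meth, unmeth, positions=None, scaffold="sc1",
                n_pairs=None) -> MethylationCallMatrix:
    """Build a matrix from explicit count arrays (sites x replicates)."""
    meth = np.atleast_2d(np.asarray(meth))
    unmeth = np.atleast_2d(np.asarray(unmeth))
    n_sites, n_reps = meth.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame({
        "scaffold": scaffold,
        "position": np.asarray(positions, dtype=np.int64),
        "strand": "+",
    })
    n_pairs = n_pairs or max(1, n_reps // 2)
    rows = []
    for m in range(1, n_pairs + 1):
        rows.append((f"NF{m}", m, "NF"))
    for m in range(1, n_pairs + 1):
        rows.append((f"CR{m}", m, "CR"))
    samples = pd.DataFrame(
        rows[:n_reps], columns=["replicate", "mother", "treatment"]
    ).set_index("replicate")
    return MethylationCallMatrix(sites, meth, unmeth, samples)
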