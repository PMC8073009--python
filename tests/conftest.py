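import numpy as np
import pandas as pd
import pytest

import ribofit as rf


@pytest.fixture(scope="session")
def sim_annotation():
    """Medium synthetic annotation + genome with mixed strands and stops."""
    cfg = rf.SimAnnotationConfig(
        n_genes=300,
        seed=1,
        frac_a_uga=0.07,
        stop_freqs={"UAA": 0.5, "UAG": 0.25, "UGA": 0.25},
    )
    return rf.gen_annotation(cfg)


@pytest.fixture(scope="session")
def uga_stress_track(sim_annotation):
    """Noiseless footprint pileup with UGA-specific queues and readthrough.

    Emulates an acute depletion of the UGA-cognate release factor: 3 queue
    peaks on a 25-nt grid at UGA stops only, 5x elevated readthrough on UGA
    genes over a 0.01 baseline.
    """
    ann, _genome = sim_annotation
    prof = rf.SimProfileConfig(
        slowdown={"UAA": 1.0, "UAG": 1.0, "UGA": 4.0},
        readthrough={"UAA": 0.01, "UAG": 0.01, "UGA": 0.05},
        noise=None,
        te_mean=3.0,
        te_sigma=0.5,
        seed=2,
    )
    track, truth = rf.gen_pileup(ann, prof)
    return track, truth


@pytest.fixture()
def two_gene_plus_annotation():
    """Two co-directional plus-strand genes with an AUGA -4 nt junction."""
    up_len, down_len = 300, 240
    up_start = 100
    up_end = up_start + up_len
    down_start = up_end - 4
    genes = pd.DataFrame(
        {
            "gene_id": ["up", "down"],
            "chrom": "chr",
            "strand": "+",
            "start": [up_start, down_start],
            "end": [up_end, down_start + down_len],
            "gene_class": "mRNA",
            "stop_codon": ["UGA", "UAA"],
            "stop_tetra": ["UGAA", "UAAG"],
            "regulons": "",
        }
    )
    size = down_start + down_len + 200
    rng = np.random.default_rng(7)
    seq = list(rng.choice(list("ACGT"), size=size))
    seq[up_end - 4 : up_end] = list("ATGA")  # start/stop overlap motif
    de = down_start + down_len
    seq[de - 3 : de] = list("TAA")
    genome = {"chr": "".join(seq)}
    return rf.GeneAnnotation(genes, chrom_sizes={"chr": size}), genome
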