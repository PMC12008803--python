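import numpy as np
import pandas as pd
import pytest

from pescreen.model import PegRNADesign, Sample, ScreenConfig, Variant

_BASES = "ACGT"


def random_seq(rng, length):
    return "".join(_BASES[i] for i in rng.integers(0, 4, length))


def make_design(pegrna_id, variant_id, rng, scaffold=None, library_bc=None,
                edit_pos=27):
    """Hand-rolled design with a single-nucleotide edit at ``edit_pos``."""
    st = random_seq(rng, 55)
    ref = st[edit_pos]
    alt = _BASES[(_BASES.index(ref) + 1) % 4]
    core = st[edit_pos - 5:edit_pos] + alt + st[edit_pos + 1:edit_pos + 6]
    while core in st:
        st = random_seq(rng, 55)
        ref = st[edit_pos]
        alt = _BASES[(_BASES.index(ref) + 1) % 4]
        core = st[edit_pos - 5:edit_pos] + alt + st[edit_pos + 1:edit_pos + 6]
    return PegRNADesign(
        pegrna_id=pegrna_id,
        variant_id=variant_id,
        spacer=random_seq(rng, 20),
        scaffold=scaffold or random_seq(rng, 30),
        extension=random_seq(rng, 25),
        st_ref=st,
        st_edit_core=core,
        pegrna_bc=random_seq(rng, 16),
        library_bc=library_bc or random_seq(rng, 10),
        features={"pbs_length": 13.0, "rtt_length": 20.0},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_library(rng):
    """Three pegRNAs programming three variants (syn / nonsense / missense)."""
    scaffold = random_seq(rng, 30)
    library_bc = random_seq(rng, 10)
    designs = [
        make_design(f"pg{i}", f"v{i}", rng, scaffold, library_bc)
        for i in range(1, 4)
    ]
    variants = [
        Variant("v1", gene="G", genomic_pos=101, consequence="synonymous",
                neutral_set=True),
        Variant("v2", gene="G", genomic_pos=102, consequence="nonsense",
                plof_set=True),
        Variant("v3", gene="G", genomic_pos=103, consequence="missense"),
    ]
    return designs, variants


@pytest.fixture
def config():
    return ScreenConfig()


def make_samples(screen_id="s1", cell_line="HAP1", coselection=False):
    return [
        Sample(f"{screen_id}_ctrl", screen_id, cell_line, coselection, 10, 1,
               "negative_control"),
        Sample(f"{screen_id}_pre", screen_id, cell_line, coselection, 10, 1,
               "pre"),
        Sample(f"{screen_id}_post", screen_id, cell_line, coselection, 34, 1,
               "post"),
    ]
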