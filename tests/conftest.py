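import numpy as np
import pytest

from gfakit import io as gio
from gfakit.fixtures import FixtureSpec, generate_fixture
from gfakit.model import (
    Assembly,
    ElementKind,
    PathElement,
    SegmentEnd,
    Side,
)


@pytest.fixture
def toy():
    """One scaffold 'ACGNNNTTG': 2 contigs of 3 bp around a 3 bp gap."""
    return gio.read_fasta(b">sc1\nACGNNNTTG\n")


def build_three_segment_scaffold(lead=2, mid1=3, mid2=4, trail=2):
    """A--B--C scaffold with terminal gaps on both ends.

    Mirrors the canonical worked example: segments A, B, C connected by
    internal gaps (A-B, B-C) plus one terminal gap on A's outer end and
    one on C's outer end.
    """
    asm = Assembly()
    a = asm.add_segment("A", "ACGTAC")
    b = asm.add_segment("B", "GGTTGG")
    c = asm.add_segment("C", "CATCAT")
    g_lead = asm.add_gap(None, SegmentEnd(a.uid, Side.HEAD), lead,
                         name="gap_lead")
    g_ab = asm.add_gap(SegmentEnd(a.uid, Side.TAIL),
                       SegmentEnd(b.uid, Side.HEAD), mid1, name="gap_ab")
    g_bc = asm.add_gap(SegmentEnd(b.uid, Side.TAIL),
                       SegmentEnd(c.uid, Side.HEAD), mid2, name="gap_bc")
    g_trail = asm.add_gap(SegmentEnd(c.uid, Side.TAIL), None, trail,
                          name="gap_trail")
    asm.add_path("scaf", [
        PathElement(ElementKind.GAP, g_lead.uid),
        PathElement(ElementKind.SEGMENT, a.uid),
        PathElement(ElementKind.GAP, g_ab.uid),
        PathElement(ElementKind.SEGMENT, b.uid),
        PathElement(ElementKind.GAP, g_bc.uid),
        PathElement(ElementKind.SEGMENT, c.uid),
        PathElement(ElementKind.GAP, g_trail.uid),
    ])
    return asm


@pytest.fixture
def abc_scaffold():
    return build_three_segment_scaffold()


def small_fixture_spec(seed, **overrides):
    """Downscaled generator settings so many fixtures stay fast."""
    defaults = dict(
        n_scaffolds=4,
        contig_len_log_mean=np.log(300),
        contig_len_log_sigma=0.8,
        gaps_per_scaffold_mean=2.0,
        gap_len_log_mean=np.log(50),
        gap_len_log_sigma=0.7,
        terminal_gap_prob=0.2,
        seed=seed,
    )
    defaults.update(overrides)
    return FixtureSpec(**defaults)


def random_assembly(seed, **overrides):
    fasta, _truth = generate_fixture(small_fixture_spec(seed, **overrides))
    return gio.read_fasta(fasta.encode())
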