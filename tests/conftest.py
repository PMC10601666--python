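import numpy as np
import pytest

from tracequant.atlas import AtlasSlice, RegionAtlas, RegionNode


def make_nodes(spec):
    """spec: list of (id, acronym, parent_id, level_tag)."""
    return {
        rid: RegionNode(rid, acr, acr, parent, tag) for rid, acr, parent, tag in spec
    }


@pytest.fixture
def tiny_atlas():
    """root(100,meta) -> STR(10,summary) -> MEA(1,leaf), BST(2,leaf); HY(11,summary) -> MPO(3,leaf)."""
    nodes = make_nodes(
        [
            (100, "ROOT", None, "meta"),
            (10, "STR", 100, "summary"),
            (11, "HY", 100, "summary"),
            (1, "MEA", 10, "leaf"),
            (2, "BST", 10, "leaf"),
            (3, "MPO", 11, "leaf"),
        ]
    )
    mask = np.zeros((20, 20), dtype=np.int64)
    mask[2:10, 2:10] = 1
    mask[10:18, 2:10] = 2
    mask[2:18, 12:18] = 3
    slices = [
        AtlasSlice(label_mask=mask, ap_mm=-1.58, pixel_size_um=10.0, midline_x=10)
    ]
    return RegionAtlas(nodes=nodes, slices=slices)
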