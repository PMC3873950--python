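"""Shared fixtures: hand-built toy systems and a small MTG file."""
from __future__ import annotations

import numpy as np
import pytest

from rootarch.model import Box, RootSegment, RootSystem


def seg(sid, parent, axis, order, base, tip, d, fr=0, frl=0.0) -> RootSegment:
    return RootSegment(
        segment_id=sid,
        parent_id=parent,
        axis_id=axis,
        order=order,
        base_xyz=np.asarray(base, dtype=float),
        tip_xyz=np.asarray(tip, dtype=float),
        diameter_m=d,
        fine_root_count=fr,
        fine_root_mean_length_m=frl,
    )


def system(*segments, **meta) -> RootSystem:
    return RootSystem(segments={s.segment_id: s for s in segments}, **meta)


@pytest.fixture
def toy_system() -> RootSystem:
    """Taproot of two segments plus one lateral: 3 segments, 2 axes."""
    return system(
        seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.05), 0.005),
        seg("S2", "S1", "A1", 1, (0, 0, -0.05), (0, 0, -0.10), 0.004),
        seg("S3", "S1", "A2", 2, (0, 0, -0.05), (0.04, 0, -0.05), 0.0012),
    )


TOY_MTG = """\
MTG-DIALECT v1
UNIT: mm
COLLAR: 0 0 0
PLANT: toy
FEATURES: XX YY ZZ Diameter FineRootN FineRootLen
DATA:
S1\t-\t0 0 -50\t5.0\t0\t0
S2\t<S1\t0 0 -100\t4.0\t0\t0
S3\t+S1\t40 0 -50\t1.2\t2\t15
"""


@pytest.fixture
def toy_mtg_path(tmp_path):
    p = tmp_path / "toy.mtg"
    p.write_text(TOY_MTG)
    return p
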