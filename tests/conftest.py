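import numpy as np
import pytest

from falffpipe import BrainMask, BoldRun, ConfoundSet, RunKey


def make_run(data, tr_s=2.0, voxel=3.0):
    data = np.asarray(data, dtype=float)
    return BoldRun(
        data=data,
        tr_s=tr_s,
        voxel_size_mm=(voxel,) * 3,
        affine=np.diag([voxel, voxel, voxel, 1.0]),
        run_id=RunKey("test"),
    )


def make_confounds(t, motion=None, flags=None, wm=None, csf=None):
    if motion is None:
        motion = np.zeros((t, 6))
    return ConfoundSet(motion=motion, outlier_flags=flags, wm_trace=wm, csf_trace=csf)


def full_mask(shape, voxel=3.0):
    return BrainMask(data=np.ones(shape, dtype=bool), affine=np.diag([voxel] * 3 + [1.0]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
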