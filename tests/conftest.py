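import numpy as np
import pytest

import focusfuse as ff


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cells_scene():
    """512x512 cell-like scene, the scaled full-reference experiment scene."""
    return ff.make_scene("cells", 512, 512, seed=1)


@pytest.fixture(scope="session")
def fig4_fusion(cells_scene):
    """Noise-free 3-band degradation + default-config fusion, computed once.

    Shared by the end-to-end fidelity, convexity/provenance and robustness
    checks so the expensive 512x512 run happens a single time per session.
    """
    synth = ff.fig4_protocol(cells_scene.reference, n_frames=3, sigma=3.0, seed=1)
    result = ff.fuse_stack(synth.stack)
    ref = cells_scene.reference
    return {
        "scene": cells_scene,
        "synth": synth,
        "result": result,
        "ssim": ff.ssim(ref, result.fused),
        "psnr": ff.psnr(ref, result.fused),
        "frame_psnrs": [ff.psnr(ref, fr) for fr in synth.stack.frames],
    }
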