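import numpy as np
import pytest

from myofuse.synthetic import SceneSpec, generate_fusion_scene


def myotube_sizes(n_inside: int) -> tuple[int, ...]:
    """Deterministically split n_inside nuclei into myotubes of 3-8 nuclei."""
    sizes: list[int] = []
    rem = n_inside
    while rem > 8:
        sizes.append(6)
        rem -= 6
    if rem >= 3:
        sizes.append(rem)
    elif rem > 0:
        sizes[-1] += rem
    return tuple(sizes)


def fusion_spec_for_index(target_pct: float, total: int, seed: int, **kw) -> SceneSpec:
    """Scene spec whose exact truth fusion index is close to target_pct."""
    small = (1, 2)
    inside = round(total * target_pct / 100)
    outside = total - inside - sum(small)
    return SceneSpec(
        n_single_nuclei=outside,
        myotubes=myotube_sizes(inside),
        small_myh_cells=small,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def small_fusion_scene():
    """One modest fusion scene shared by several end-to-end tests."""
    spec = SceneSpec(
        height_px=768,
        width_px=768,
        n_single_nuclei=30,
        myotubes=(5, 4, 3),
        small_myh_cells=(1, 2),
        seed=3,
    )
    return spec, generate_fusion_scene(spec)


def brute_force_particles(labels: np.ndarray, pixel_size_um: float) -> dict:
    """Independent per-pixel tally of counts, areas, centroids per label."""
    tally: dict[int, list] = {}
    h, w = labels.shape
    for r in range(h):
        for c in range(w):
            k = int(labels[r, c])
            if k == 0:
                continue
            rec = tally.setdefault(k, [0, 0.0, 0.0])
            rec[0] += 1
            rec[1] += r
            rec[2] += c
    return {
        k: {
            "pixel_count": n,
            "area_um2": n * pixel_size_um**2,
            "centroid": (rs / n, cs / n),
        }
        for k, (n, rs, cs) in tally.items()
    }
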