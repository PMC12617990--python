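"""Deliberately naive, loop-based reimplementation of the QC rules.

Kept independent of the package internals so it can serve as a
brute-force oracle: plain Python loops, no shared helpers.
"""

import math

import numpy as np


def naive_threshold(b, alpha=0.3, f=0.02, adc=0.002):
    return alpha * (1.0 - math.exp(-b * adc)) + f


def naive_volume_flags(data, masks, bvals, cfg, slice_axis=2):
    """Per-volume (flag_dropout, flag_volume, flag_cropped) triples.

    Reference is volume 0's mask (assumed non-empty); an empty mask
    yields (False, True, False) — red via the volume rule.
    """
    nx, ny, nz, t = data.shape
    shape = (nx, ny, nz)
    ref_count = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if masks[i, j, k, 0]:
                    ref_count += 1
    assert ref_count > 0
    flags = []
    for v in range(t):
        voxels = []
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if masks[i, j, k, v]:
                        voxels.append((i, j, k))
        if not voxels:
            flags.append((False, True, False))
            continue
        vol_mean = sum(data[i, j, k, v] for i, j, k in voxels) / len(voxels)
        dropout = False
        for s in range(shape[slice_axis]):
            sl = [(i, j, k) for i, j, k in voxels
                  if (i, j, k)[slice_axis] == s]
            if len(sl) < cfg.min_mask_voxels_per_slice:
                continue
            m = sum(data[i, j, k, v] for i, j, k in sl) / len(sl)
            if m < (1.0 - cfg.slice_deficit) * vol_mean:
                dropout = True
        thr = naive_threshold(bvals[v], cfg.alpha, cfg.f_offset, cfg.adc_ref)
        vol_flag = abs(len(voxels) - ref_count) / ref_count > thr
        cropped = False
        for i, j, k in voxels:
            if (i in (0, nx - 1) or j in (0, ny - 1) or k in (0, nz - 1)):
                cropped = True
                break
        flags.append((dropout, vol_flag,
                      cropped and cfg.boundary_fraction_tol == 0.0))
    return flags


def naive_red_set(data, masks, bvals, cfg, slice_axis=2):
    flags = naive_volume_flags(np.asarray(data), np.asarray(masks),
                               np.asarray(bvals), cfg, slice_axis)
    return {i for i, (a, b, c) in enumerate(flags) if a or b or c}
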