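"""Independent brute-force oracles shared by unit and acceptance tests."""

import numpy as np


def shadow_oracle(rasters, sun, max_radius=None, eval_height=0.0):
    """Exhaustive per-cell ray marching to the sun.

    Scalar, cell-by-cell implementation of the same discrete geometry as
    the production caster (one cell-size step per iteration, nearest-cell
    sampling): intentionally simple and slow.  Returns
    (building_shadow, veg_shadow-only) boolean masks.
    """
    cs = rasters.cell_size
    dem, dsm, chm, trunk = rasters.dem, rasters.dsm, rasters.chm, rasters.trunk
    veg_top = dem + chm
    veg_base = dem + trunk
    nrows, ncols = dem.shape
    tan_elev = np.tan(np.radians(sun.elevation))
    azr = np.radians(sun.azimuth)
    sin_az, cos_az = np.sin(azr), np.cos(azr)
    zmax = max(float(dsm.max()), float(veg_top.max()))
    if max_radius is None:
        k_max = int(np.ceil(np.hypot(nrows, ncols)))
    else:
        k_max = int(np.floor(max_radius / cs))

    ks = np.arange(1, k_max + 1)
    drs = np.rint(-ks * cos_az).astype(int)
    dcs = np.rint(ks * sin_az).astype(int)

    bshad = np.zeros((nrows, ncols), dtype=bool)
    vshad = np.zeros((nrows, ncols), dtype=bool)
    for r in range(nrows):
        for c in range(ncols):
            z0 = dem[r, c] + eval_height
            hit_b = dsm[r, c] > z0 + 1e-9
            hit_v = chm[r, c] > 0 and veg_base[r, c] <= z0 <= veg_top[r, c]
            for k, dr, dc in zip(ks, drs, dcs):
                zk = z0 + k * cs * tan_elev
                if zk > zmax:
                    break
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nrows and 0 <= cc < ncols):
                    continue
                if dsm[rr, cc] > zk:
                    hit_b = True
                if chm[rr, cc] > 0 and veg_base[rr, cc] <= zk <= veg_top[rr, cc]:
                    hit_v = True
            bshad[r, c] = hit_b
            vshad[r, c] = hit_v
    return bshad, vshad & ~bshad
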