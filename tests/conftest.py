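import numpy as np
import pytest

from argoshr.geo import CRS, Fix, Track


@pytest.fixture
def rng():
    return np.random.default_rng(20120701)


@pytest.fixture
def origin():
    return CRS(-80.0, 73.0)


def planar_fix(x, y, t, crs=CRS(-80.0, 73.0), lc=None, source="gps", fid="f"):
    """Build a Fix whose projected position is (x, y) metres from the frame
    origin — convenient for geometry-level tests. (Projection correctness
    itself is covered by independent oracles in test_geo.)"""
    from argoshr.geo import unproject_xy

    lon, lat = unproject_xy(x, y, crs)
    return Fix(id=fid, t=float(t), lon=float(lon), lat=float(lat), lc=lc, source=source)


def planar_track(coords, times, crs=CRS(-80.0, 73.0), lc=None, source="gps", sid="trk"):
    fixes = [
        planar_fix(x, y, t, crs=crs, lc=lc, source=source, fid=sid)
        for (x, y), t in zip(coords, times)
    ]
    return Track(sid, fixes)
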