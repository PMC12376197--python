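"""Great-circle geometry helpers shared by the spatial stages."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_distances_km(lat, lon, lat2=None, lon2=None):
    """Distance matrix (km) between two point sets; symmetric if one set given."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat2 is None:
        lat2, lon2 = lat, lon
    else:
        lat2 = np.asarray(lat2, dtype=float)
        lon2 = np.asarray(lon2, dtype=float)
    return haversine_km(lat[:, None], lon[:, None], lat2[None, :], lon2[None, :])
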