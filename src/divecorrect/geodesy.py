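"""WGS-84 geodesic and local-metric helpers.

Distances and azimuths that enter reported quantities (ground speed,
path lengths, straightness) use the ellipsoidal geodesic (Vincenty's
formulae).  Inner-loop position propagation and interpolation-weight
distances use a local equirectangular metric, which is accurate to well
under a metre at the sub-daily step sizes involved.
"""

from __future__ import annotations

import math

import numpy as np

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)
_E2 = WGS84_F * (2.0 - WGS84_F)  # first eccentricity squared

_MAX_ITER = 200
_CONV = 1e-12


def wrap_lon(lon):
    """Map longitudes to [-180, 180); values already in range pass
    through exactly."""
    arr = np.asarray(lon, dtype=float)
    wrapped = np.where(
        (arr >= -180.0) & (arr < 180.0), arr, (arr + 180.0) % 360.0 - 180.0
    )
    return wrapped if arr.ndim else float(wrapped)


def meters_per_degree(lat_deg: float) -> tuple[float, float]:
    """(metres per degree of longitude, metres per degree of latitude)
    on the WGS-84 ellipsoid at the given latitude."""
    phi = math.radians(lat_deg)
    s2 = math.sin(phi) ** 2
    nu = WGS84_A / math.sqrt(1.0 - _E2 * s2)          # prime vertical radius
    m = WGS84_A * (1.0 - _E2) / (1.0 - _E2 * s2) ** 1.5  # meridional radius
    return math.radians(1.0) * nu * math.cos(phi), math.radians(1.0) * m


def geodesic_inverse(lon1: float, lat1: float, lon2: float, lat2: float) -> tuple[float, float]:
    """Geodesic distance (m) and forward azimuth (deg clockwise from north)
    from point 1 to point 2 (Vincenty's inverse formula)."""
    if lon1 == lon2 and lat1 == lat2:
        return 0.0, float("nan")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1.0 - WGS84_F) * math.tan(phi1))
    U2 = math.atan((1.0 - WGS84_F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(_MAX_ITER):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.sqrt(
            (cosU2 * sin_lam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
        )
        if sin_sigma == 0.0:
            return 0.0, float("nan")
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        if cos2_alpha == 0.0:  # equatorial line
            cos_2sigma_m = 0.0
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = WGS84_F / 16.0 * cos2_alpha * (4.0 + WGS84_F * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * WGS84_F * sin_alpha * (
            sigma
            + C * sin_sigma * (cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < _CONV:
            break

    u2 = cos2_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    delta_sigma = B * sin_sigma * (
        cos_2sigma_m
        + B / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2)
            - B / 6.0 * cos_2sigma_m * (-3.0 + 4.0 * sin_sigma**2) * (-3.0 + 4.0 * cos_2sigma_m**2)
        )
    )
    dist = WGS84_B * A * (sigma - delta_sigma)
    az = math.degrees(
        math.atan2(cosU2 * math.sin(lam), cosU1 * sinU2 - sinU1 * cosU2 * math.cos(lam))
    )
    return dist, az % 360.0


def geodesic_direct(lon1: float, lat1: float, azimuth_deg: float, distance_m: float) -> tuple[float, float]:
    """Destination point from start, initial azimuth and geodesic distance
    (Vincenty's direct formula)."""
    if distance_m == 0.0:
        return lon1, lat1
    phi1 = math.radians(lat1)
    alpha1 = math.radians(azimuth_deg)
    U1 = math.atan((1.0 - WGS84_F) * math.tan(phi1))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sin_alpha1, cos_alpha1 = math.sin(alpha1), math.cos(alpha1)
    sigma1 = math.atan2(math.tan(U1), cos_alpha1)
    sin_alpha = cosU1 * sin_alpha1
    cos2_alpha = 1.0 - sin_alpha**2
    u2 = cos2_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))

    sigma = distance_m / (WGS84_B * A)
    for _ in range(_MAX_ITER):
        cos_2sigma_m = math.cos(2.0 * sigma1 + sigma)
        sin_sigma, cos_sigma = math.sin(sigma), math.cos(sigma)
        delta_sigma = B * sin_sigma * (
            cos_2sigma_m
            + B / 4.0 * (
                cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2)
                - B / 6.0 * cos_2sigma_m * (-3.0 + 4.0 * sin_sigma**2) * (-3.0 + 4.0 * cos_2sigma_m**2)
            )
        )
        sigma_prev = sigma
        sigma = distance_m / (WGS84_B * A) + delta_sigma
        if abs(sigma - sigma_prev) < _CONV:
            break

    sin_sigma, cos_sigma = math.sin(sigma), math.cos(sigma)
    cos_2sigma_m = math.cos(2.0 * sigma1 + sigma)
    phi2 = math.atan2(
        sinU1 * cos_sigma + cosU1 * sin_sigma * cos_alpha1,
        (1.0 - WGS84_F)
        * math.sqrt(sin_alpha**2 + (sinU1 * sin_sigma - cosU1 * cos_sigma * cos_alpha1) ** 2),
    )
    lam = math.atan2(
        sin_sigma * sin_alpha1, cosU1 * cos_sigma - sinU1 * sin_sigma * cos_alpha1
    )
    C = WGS84_F / 16.0 * cos2_alpha * (4.0 + WGS84_F * (4.0 - 3.0 * cos2_alpha))
    L = lam - (1.0 - C) * WGS84_F * sin_alpha * (
        sigma
        + C * sin_sigma * (cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2))
    )
    lon2 = lon1 + math.degrees(L)
    return float(wrap_lon(lon2)), math.degrees(phi2)


def local_step(lon: float, lat: float, dx_m: float, dy_m: float) -> tuple[float, float]:
    """Advance a position by east/north metre offsets in the local
    equirectangular metric evaluated at the current latitude."""
    mlon, mlat = meters_per_degree(lat)
    return float(wrap_lon(lon + dx_m / mlon)), lat + dy_m / mlat


def local_displacement(lon1: float, lat1: float, lon2: float, lat2: float) -> tuple[float, float]:
    """(east, north) metre offsets from point 1 to point 2 in the local
    metric at the mean latitude."""
    mlon, mlat = meters_per_degree(0.5 * (lat1 + lat2))
    dlon = float(wrap_lon(lon2 - lon1))
    return dlon * mlon, (lat2 - lat1) * mlat


def great_circle_interpolate(lon1, lat1, lon2, lat2, frac):
    """Point a fraction ``frac`` of the way along the great circle from
    point 1 to point 2 (spherical slerp; exact at frac 0 and 1)."""
    if frac == 0.0 or (lon1 == lon2 and lat1 == lat2):
        return lon1, lat1
    if frac == 1.0:
        return lon2, lat2
    p1 = _unit(lon1, lat1)
    p2 = _unit(lon2, lat2)
    omega = math.acos(max(-1.0, min(1.0, float(np.dot(p1, p2)))))
    if omega == 0.0:
        return lon1, lat1
    s = math.sin(omega)
    p = (math.sin((1.0 - frac) * omega) / s) * p1 + (math.sin(frac * omega) / s) * p2
    p /= np.linalg.norm(p)
    lat = math.degrees(math.asin(p[2]))
    lon = math.degrees(math.atan2(p[1], p[0]))
    return float(wrap_lon(lon)), lat


def _unit(lon, lat):
    lam, phi = math.radians(lon), math.radians(lat)
    return np.array(
        [math.cos(phi) * math.cos(lam), math.cos(phi) * math.sin(lam), math.sin(phi)]
    )


def path_length(lons, lats) -> float:
    """Summed geodesic length (m) of a polyline of positions."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return float(
        sum(
            geodesic_inverse(lons[i], lats[i], lons[i + 1], lats[i + 1])[0]
            for i in range(len(lons) - 1)
        )
    )
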