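"""WGS84 <-> UTM coordinate transforms.

Implements the transverse Mercator projection with a 6th-order
Krüger series in the third flattening (Karney 2011 formulation),
which is accurate to well below a millimetre anywhere inside a UTM
zone.  Only the northern hemisphere is handled (no false northing
offset for the south), which covers the mid-latitude study systems
this package targets.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["utm_zone", "to_utm", "to_wgs84"]

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E = np.sqrt(_F * (2.0 - _F))
_N3 = _F / (2.0 - _F)  # third flattening n

_K0 = 0.9996
_FALSE_EASTING = 500_000.0

# Rectifying radius A = a/(1+n) * (1 + n^2/4 + n^4/64 + n^6/256)
_ARAD = _A / (1.0 + _N3) * (1.0 + _N3**2 / 4.0 + _N3**4 / 64.0 + _N3**6 / 256.0)

_n = _N3
_ALPHA = np.array(
    [
        _n / 2 - 2 * _n**2 / 3 + 5 * _n**3 / 16 + 41 * _n**4 / 180
        - 127 * _n**5 / 288 + 7891 * _n**6 / 37800,
        13 * _n**2 / 48 - 3 * _n**3 / 5 + 557 * _n**4 / 1440
        + 281 * _n**5 / 630 - 1983433 * _n**6 / 1935360,
        61 * _n**3 / 240 - 103 * _n**4 / 140 + 15061 * _n**5 / 26880
        + 167603 * _n**6 / 181440,
        49561 * _n**4 / 161280 - 179 * _n**5 / 168 + 6601661 * _n**6 / 7257600,
        34729 * _n**5 / 80640 - 3418889 * _n**6 / 1995840,
        212378941 * _n**6 / 319334400,
    ]
)
_BETA = np.array(
    [
        _n / 2 - 2 * _n**2 / 3 + 37 * _n**3 / 96 - _n**4 / 360
        - 81 * _n**5 / 512 + 96199 * _n**6 / 604800,
        _n**2 / 48 + _n**3 / 15 - 437 * _n**4 / 1440
        + 46 * _n**5 / 105 - 1118711 * _n**6 / 3870720,
        17 * _n**3 / 480 - 37 * _n**4 / 840 - 209 * _n**5 / 4480
        + 5569 * _n**6 / 90720,
        4397 * _n**4 / 161280 - 11 * _n**5 / 504 - 830251 * _n**6 / 7257600,
        4583 * _n**5 / 161280 - 108847 * _n**6 / 3991680,
        20648693 * _n**6 / 638668800,
    ]
)
_J = np.arange(1, 7)


def utm_zone(lon: float) -> int:
    """UTM zone number (1-60) for a longitude in degrees."""
    return int((float(lon) + 180.0) // 6.0) % 60 + 1


def _central_meridian(zone: int) -> float:
    return (zone - 1) * 6.0 - 180.0 + 3.0


def to_utm(lon, lat, zone: int | None = None):
    """Project WGS84 lon/lat (degrees) to UTM easting/northing (metres).

    Parameters
    ----------
    lon, lat : array-like, degrees
    zone : UTM zone; defaults to the zone of the mean longitude.

    Returns
    -------
    (easting, northing, zone)
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if zone is None:
        zone = utm_zone(float(np.mean(lon)))
    lam0 = np.radians(_central_meridian(zone))
    lam = np.radians(lon) - lam0
    if np.any(np.abs(np.degrees(lam)) > 6.0):
        warnings.warn(
            f"coordinates fall outside UTM zone {zone} (+/-3 deg of the "
            "central meridian); projection error grows away from the zone",
            stacklevel=2,
        )
    phi = np.radians(lat)

    s = np.sin(phi)
    # conformal latitude via tau -> tau'
    t = np.sinh(np.arctanh(s) - _E * np.arctanh(_E * s))
    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arcsinh(np.sin(lam) / np.hypot(t, np.cos(lam)))

    jxi = 2.0 * np.multiply.outer(xi_p, _J)
    jeta = 2.0 * np.multiply.outer(eta_p, _J)
    xi = xi_p + np.sum(_ALPHA * np.sin(jxi) * np.cosh(jeta), axis=-1)
    eta = eta_p + np.sum(_ALPHA * np.cos(jxi) * np.sinh(jeta), axis=-1)

    easting = _FALSE_EASTING + _K0 * _ARAD * eta
    northing = _K0 * _ARAD * xi
    return easting, northing, zone


def to_wgs84(easting, northing, zone: int):
    """Inverse-project UTM easting/northing (metres, northern hemisphere)
    back to WGS84 lon/lat in degrees."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    xi = northing / (_K0 * _ARAD)
    eta = (easting - _FALSE_EASTING) / (_K0 * _ARAD)

    jxi = 2.0 * np.multiply.outer(xi, _J)
    jeta = 2.0 * np.multiply.outer(eta, _J)
    xi_p = xi - np.sum(_BETA * np.sin(jxi) * np.cosh(jeta), axis=-1)
    eta_p = eta - np.sum(_BETA * np.cos(jxi) * np.sinh(jeta), axis=-1)

    chi = np.arcsin(np.sin(xi_p) / np.cosh(eta_p))
    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))

    # invert the conformal latitude by fixed-point iteration
    phi = chi
    a_chi = np.arctanh(np.sin(chi))
    for _ in range(12):
        phi = np.arcsin(np.tanh(a_chi + _E * np.arctanh(_E * np.sin(phi))))

    lon = np.degrees(lam) + _central_meridian(zone)
    lat = np.degrees(phi)
    return lon, lat
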