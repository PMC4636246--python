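"""Published field-calibration statistics for Argos location error in open tundra.

These constants summarize a dual Argos/GPS accuracy experiment at ~73N
(static transmitters on stakes; mobile transmitters carried on foot). They
are the fit targets for the synthetic error model and the source of the
session-size and location-class-mix defaults used throughout the simulations.
They are inputs to this package, not outputs of it.
"""

from __future__ import annotations

from .error_stats import LCErrorSummary

# columns: lc, n, proportion, mean, sd, mean_x, sd_x, mean_y, sd_y, median, p68, p90
_STATIC_ROWS = [
    ("3", 964, 0.458, 259, 208, 171, 165, 162, 166, 213, 298, 469),
    ("2", 622, 0.295, 456, 359, 306, 301, 283, 270, 357, 517, 953),
    ("1", 232, 0.110, 773, 607, 540, 464, 471, 486, 588, 920, 1613),
    ("0", 45, 0.021, 5330, 17085, 4152, 12852, 3123, 11321, 1454, 2475, 8253),
    ("A", 126, 0.060, 640, 866, 397, 483, 419, 770, 397, 618, 1128),
    ("B", 117, 0.056, 1195, 2143, 694, 1371, 831, 1723, 478, 787, 2580),
    ("Total", 2106, 1.0, 557, 2656, 379, 1992, 348, 1771, 299, 440, 978),
]

_MOBILE_ROWS = [
    ("3", 267, 0.2094, 556, 409, 369, 310, 347, 353, 470, 643, 1007),
    ("2", 438, 0.3435, 822, 726, 533, 551, 525, 583, 624, 887, 1593),
    ("1", 327, 0.2565, 2007, 1946, 1359, 1593, 1253, 1365, 1430, 2124, 3933),
    ("0", 161, 0.1263, 6270, 9402, 4601, 8328, 3757, 4805, 3845, 5780, 12850),
    ("A", 27, 0.0212, 1988, 2166, 1350, 1750, 1144, 1575, 954, 2351, 4853),
    ("B", 55, 0.0431, 5028, 16059, 3058, 12025, 3502, 10819, 1233, 2184, 8367),
    ("Total", 1275, 1.0, 1964, 5189, 1350, 4191, 1224, 3146, 864, 1433, 4105),
]


def _build(rows):
    return {
        r[0]: LCErrorSummary(
            lc=r[0], n=r[1], proportion=r[2], mean=r[3], sd=r[4], mean_x=r[5],
            sd_x=r[6], mean_y=r[7], sd_y=r[8], median=r[9], p68=r[10], p90=r[11],
        )
        for r in rows
    }


#: Static-transmitter error statistics per location class.
STATIC: dict[str, LCErrorSummary] = _build(_STATIC_ROWS)

#: Mobile-transmitter (walking pace) error statistics per location class.
MOBILE: dict[str, LCErrorSummary] = _build(_MOBILE_ROWS)

#: Location-class mix observed on mobile transmitters (fractions of fixes).
MOBILE_LC_MIX: dict[str, float] = {
    lc: MOBILE[lc].n / MOBILE["Total"].n for lc in ("3", "2", "1", "0", "A", "B")
}

#: Class mix within the best-two-classes (LC3+LC2) subset of the mobile data.
LC32_MIX: dict[str, float] = {
    "3": MOBILE["3"].n / (MOBILE["3"].n + MOBILE["2"].n),
    "2": MOBILE["2"].n / (MOBILE["3"].n + MOBILE["2"].n),
}

#: Fixes obtained per mobile session: mean and SD.
SESSION_SIZE = (64.0, 20.0)

#: LC3+LC2 fixes per mobile session: mean and SD.
LC32_SESSION_SIZE = (35.0, 19.0)
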