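"""Independent reference implementations used only as test oracles.

These deliberately take different routes from the package code: the
episode scanner is a regular-expression match over a per-female minute
string, the distance oracle is a haversine great-circle formula, and the
I&SI oracle enumerates every permutation.
"""

import itertools
import math
import re

import numpy as np
import pandas as pd

EPISODE_RE = re.compile(r"q{6,}(?:\.{1,2}q+)*")


def regex_segment(scans: pd.DataFrame):
    """All MG episodes of one male-day as (female, start_minute, end_minute).

    Builds, per female, a string with one character per minute of the
    observed span ('q' = following that female at <= 10 m, '.' other) and
    matches runs of >= 6 q's bridged by gaps of at most two minutes.
    """
    ts = pd.to_datetime(scans["timestamp"])
    minutes = (ts.dt.hour * 60 + ts.dt.minute).to_numpy()
    lo, hi = minutes.min(), minutes.max()
    females = sorted(
        {str(f) for f in scans["following_female"] if f is not None and not pd.isna(f)}
    )
    episodes = []
    for female in females:
        chars = ["."] * (hi - lo + 1)
        for m, f, c in zip(minutes, scans["following_female"], scans["female_distance_le_10m"]):
            close = c is not None and not pd.isna(c) and bool(c)
            if f is not None and not pd.isna(f) and str(f) == female and close:
                chars[m - lo] = "q"
        for match in EPISODE_RE.finditer("".join(chars)):
            episodes.append((female, lo + match.start(), lo + match.end() - 1))
    episodes.sort(key=lambda e: e[1])
    return episodes


def haversine_m(lon1, lat1, lon2, lat2, radius=6_371_008.8):
    """Great-circle distance in metres between two lon/lat points."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * radius * math.asin(math.sqrt(a))


def exhaustive_isi(dom: np.ndarray):
    """Best (I, SI) and one optimal order by enumerating all permutations."""
    n = dom.shape[0]
    best = None
    best_order = None
    for perm in itertools.permutations(range(n)):
        i_count = 0
        si = 0
        for a in range(n - 1):
            for b in range(a + 1, n):
                if dom[perm[b], perm[a]]:
                    i_count += 1
                    si += b - a
        score = (i_count, si)
        if best is None or score < best:
            best, best_order = score, perm
    return best, best_order
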