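"""Seed derivation and small calendar/random helpers."""
from __future__ import annotations

import calendar
import datetime
import hashlib
import random


def derive_seed(*parts: object) -> int:
    """Stable sub-seed from arbitrary tokens (independent of hash randomization)."""
    payload = "\x1f".join(str(p) for p in parts).encode()
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


def rand_date(rng: random.Random, lo: datetime.date, hi: datetime.date) -> datetime.date:
    """Uniform date in [lo, hi], both ends inclusive."""
    if hi < lo:
        raise ValueError(f"empty date range {lo}..{hi}")
    return lo + datetime.timedelta(days=rng.randint(0, (hi - lo).days))


def rand_day_in_month(rng: random.Random, year: int, month: int) -> datetime.date:
    return datetime.date(year, month, rng.randint(1, calendar.monthrange(year, month)[1]))


def add_years(d: datetime.date, n: int) -> datetime.date:
    """Shift by whole years, clamping Feb 29 to Feb 28."""
    try:
        return d.replace(year=d.year + n)
    except ValueError:
        return d.replace(year=d.year + n, day=28)


def add_months(d: datetime.date, n: int) -> datetime.date:
    """Shift by whole months, clamping the day to the target month's length."""
    idx = d.year * 12 + (d.month - 1) + n
    year, month = idx // 12, idx % 12 + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return datetime.date(year, month, day)
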