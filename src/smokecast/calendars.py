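"""Holiday calendars.

Holiday awareness matters because many pharmacies close on statutory
holidays, depressing dispensation counts the way weekends do.  The package
accepts any explicit set of dates; a rule-based British Columbia statutory
calendar is built in for convenience and for the synthetic scenarios.
"""

from __future__ import annotations

import datetime as dt

__all__ = ["bc_holidays", "resolve_holidays"]


def _easter(year: int) -> dt.date:
    # Butcher's algorithm (Gregorian)
    a = year % 19
    b, c = divmod(year, 100)
    d, e = divmod(b, 4)
    g = (8 * b + 13) // 25
    h = (19 * a + b - d - g + 15) % 30
    i, k = divmod(c, 4)
    l = (32 + 2 * e + 2 * i - h - k) % 7
    m = (a + 11 * h + 22 * l) // 451
    month, day = divmod(h + l - 7 * m + 114, 31)
    return dt.date(year, month, day + 1)


def _nth_weekday(year: int, month: int, weekday: int, n: int) -> dt.date:
    d = dt.date(year, month, 1)
    offset = (weekday - d.weekday()) % 7 + 7 * (n - 1)
    return d + dt.timedelta(days=offset)


def bc_holidays(year: int) -> set[dt.date]:
    """British Columbia statutory holidays for one year."""
    mon = 0
    days = {
        dt.date(year, 1, 1),                      # New Year's Day
        _easter(year) - dt.timedelta(days=2),     # Good Friday
        dt.date(year, 7, 1),                      # Canada Day
        _nth_weekday(year, 8, mon, 1),            # BC Day
        _nth_weekday(year, 9, mon, 1),            # Labour Day
        _nth_weekday(year, 10, mon, 2),           # Thanksgiving
        dt.date(year, 11, 11),                    # Remembrance Day
        dt.date(year, 12, 25),                    # Christmas Day
    }
    # Victoria Day: Monday preceding May 25
    d = dt.date(year, 5, 24)
    days.add(d - dt.timedelta(days=d.weekday()))
    if year >= 2013:  # Family Day (3rd Monday of Feb from 2019, 2nd before)
        days.add(_nth_weekday(year, 2, mon, 3 if year >= 2019 else 2))
    return days


def resolve_holidays(spec, years) -> set[dt.date]:
    """Turn a holiday specification into a concrete set of dates.

    ``spec`` may be the string ``"bc"``, ``"none"``/None, or an iterable of
    dates / ISO date strings.
    """
    if spec is None or spec == "none":
        return set()
    if spec == "bc":
        out: set[dt.date] = set()
        for y in years:
            out |= bc_holidays(int(y))
        return out
    out = set()
    for d in spec:
        out.add(d if isinstance(d, dt.date) else dt.date.fromisoformat(str(d)))
    return out
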