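"""Naive re-derivation of the region-admission iteration, used as an oracle.

Deliberately written as straight-line loops over the rule description,
independent of the package implementation: levels 1, 2, 4, 8 in order,
row-major blocks from the south-west corner (8-degree tiles truncated to 4
at the far edges), candidate series summed over not-yet-assigned cells,
the three admission tests, per-country splitting of passing blocks, and a
final relaxed pass over leftover 8-degree blocks.
"""
import numpy as np


def oracle_fcrs(monthly_values, years, mask, e_min, nonzero_year_frac=0.90,
                cv_max=2.0, e_min_8r=0.12):
    """Return (id_grid, levels, countries) exactly per the iteration rules.

    monthly_values: (n_months, n_lat, n_lon) with n_months = 12 * len(years).
    """
    n_lat, n_lon = mask.shape
    n_years = len(years)
    annual = np.zeros((n_years, n_lat, n_lon))
    for k in range(n_years):
        annual[k] = np.nan_to_num(monthly_values[12 * k:12 * (k + 1)]).sum(axis=0)

    def blocks(size):
        out = []
        r = 0
        while r < n_lat:
            rtop = min(r + size, n_lat)
            c = 0
            while c < n_lon:
                ctop = min(c + size, n_lon)
                out.append((r, rtop, c, ctop))
                c = ctop
            r = rtop
        return out

    def passes(series):
        mean = series.mean()
        if mean < e_min:
            return False
        if np.mean(series > 0) < nonzero_year_frac:
            return False
        if mean <= 0:
            return False
        if series.std(ddof=1) / mean >= cv_max:
            return False
        return True

    ids = np.zeros((n_lat, n_lon), dtype=int)
    assigned = np.zeros((n_lat, n_lon), dtype=bool)
    levels = {}
    countries = {}
    next_id = 1

    def assign(cells, level):
        nonlocal next_id
        codes = sorted({int(mask[i, j]) for (i, j) in cells})
        for code in codes:
            group = [(i, j) for (i, j) in cells if mask[i, j] == code]
            for (i, j) in group:
                ids[i, j] = next_id
                assigned[i, j] = True
            levels[next_id] = level
            countries[next_id] = code
            next_id += 1

    for level, size in (("1", 1), ("2", 2), ("4", 4), ("8", 8)):
        for (r0, r1, c0, c1) in blocks(size):
            cells = [(i, j) for i in range(r0, r1) for j in range(c0, c1)
                     if not assigned[i, j]]
            if not cells:
                continue
            series = np.zeros(n_years)
            for k in range(n_years):
                for (i, j) in cells:
                    series[k] += annual[k, i, j]
            if passes(series):
                assign(cells, level)

    for (r0, r1, c0, c1) in blocks(8):
        cells = [(i, j) for i in range(r0, r1) for j in range(c0, c1)
                 if not assigned[i, j]]
        if not cells:
            continue
        total = 0.0
        for k in range(n_years):
            for (i, j) in cells:
                total += annual[k, i, j]
        if total / n_years > e_min_8r:
            assign(cells, "8r")

    return ids, levels, countries
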