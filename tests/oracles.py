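"""Independent brute-force oracles used to validate rule discovery.

Everything here works by direct enumeration over raw cell grids (lists of
lists with 1/0/None), deliberately sharing no code with the library's
counting or search machinery.
"""

from itertools import combinations


def cells_of(matrix):
    """Extract (unit × column) cells and column names from a
    SatisfactionMatrix without using its counting helpers."""
    names = matrix.column_names
    grid = []
    for i in range(matrix.N):
        row = []
        for j in range(len(names)):
            v = int(matrix.data[i, j])
            row.append(None if v < 0 else v)
        grid.append(row)
    sibs = {n: set(matrix.siblings(n)) for n in names}
    return grid, names, sibs


def brute_counts(grid, names, X, y):
    """(nX, nY, nXY, N) over units with no missing cell among X ∪ {y}."""
    idx = {n: j for j, n in enumerate(names)}
    cols = [idx[c] for c in X] + [idx[y]]
    n = nx = ny = nxy = 0
    for row in grid:
        if any(row[j] is None for j in cols):
            continue
        n += 1
        x_true = all(row[idx[c]] == 1 for c in X)
        y_true = row[idx[y]] == 1
        nx += x_true
        ny += y_true
        nxy += x_true and y_true
    return nx, ny, nxy, n


def brute_rules_11(matrix, min_support, min_confidence):
    """All ordered non-sibling pairs passing the thresholds, with exact
    (support, confidence) fractions."""
    grid, names, sibs = cells_of(matrix)
    out = {}
    for x in names:
        for y in names:
            if y == x or y in sibs[x]:
                continue
            nx, ny, nxy, n = brute_counts(grid, names, [x], y)
            if nx == 0 or n == 0:
                continue
            sup, conf = nxy / n, nxy / nx
            if sup >= min_support - 1e-12 and conf >= min_confidence - 1e-12:
                out[(frozenset([x]), y)] = (sup, conf)
    return out


def _violators(grid, names, sibs, y):
    """True-column sets at units where y is present and false."""
    idx = {n: j for j, n in enumerate(names)}
    fam = set()
    for row in grid:
        if row[idx[y]] == 0:
            fam.add(frozenset(n for n in names
                              if n not in sibs[y] and row[idx[n]] == 1))
    return fam


def brute_exact_n1(matrix, y, max_lhs, min_support):
    """Inclusion-minimal LHSs with no counterexample unit, by direct
    subset enumeration (the canonical cover for one consequent)."""
    grid, names, sibs = cells_of(matrix)
    fam = _violators(grid, names, sibs, y)
    universe = sorted(n for n in names if n not in sibs[y])
    no_violation = []
    for k in range(0, max_lhs + 1):
        for X in combinations(universe, k):
            Xs = frozenset(X)
            if not any(Xs <= s for s in fam):
                no_violation.append(Xs)
    minimal = [X for X in no_violation
               if not any(o < X for o in no_violation)]
    out = set()
    for X in minimal:
        nx, _, nxy, n = brute_counts(grid, names, sorted(X), y)
        if nx == 0 or n == 0:
            continue
        if nxy / n >= min_support - 1e-12:
            out.add(X)
    return out


def brute_approx_n1(matrix, y, max_lhs, min_support, min_confidence):
    """Inclusion-maximal non-exact LHSs of size ≤ max_lhs passing the
    thresholds (the size-capped Gottlob–Libkin cover for one consequent)."""
    grid, names, sibs = cells_of(matrix)
    fam = _violators(grid, names, sibs, y)
    universe = sorted(n for n in names if n not in sibs[y])
    non_exact = []
    for k in range(1, max_lhs + 1):
        for X in combinations(universe, k):
            Xs = frozenset(X)
            if any(Xs <= s for s in fam):
                non_exact.append(Xs)
    maximal = [X for X in non_exact if not any(X < o for o in non_exact)]
    out = set()
    for X in maximal:
        nx, _, nxy, n = brute_counts(grid, names, sorted(X), y)
        if nx == 0 or n == 0:
            continue
        if (nxy / n >= min_support - 1e-12
                and min_confidence - 1e-12 <= nxy / nx < 1 - 1e-12):
            out.add(X)
    return out


def brute_transversals(family):
    """All inclusion-minimal hitting sets by full subset enumeration."""
    fam = [frozenset(e) for e in family]
    if not fam:
        return [frozenset()]
    universe = sorted(set().union(*fam))
    hitting = []
    for k in range(len(universe) + 1):
        for s in combinations(universe, k):
            if all(set(s) & e for e in fam):
                hitting.append(frozenset(s))
    minimal = [h for h in hitting if not any(o < h for o in hitting)]
    return sorted(set(minimal), key=lambda s: (len(s), tuple(sorted(s))))
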