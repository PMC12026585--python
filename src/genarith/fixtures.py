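"""Deterministic fixture generation and the brute-force Hilbert oracle.

Fixtures are plain-text only: Normaliz-style cone files with brute-forced
reference bases, cascade model JSON documents with verified steady states, and
a couple of hand-written Normaliz output files for the parser.  Everything is
reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

import itertools
import json
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from ._intlinalg import dot, frac_rank
from .hilbert_monoid import RationalCone, write_normaliz
from .powerlaw_cascade import (build_end_product_cascade, evaluate_rates,
                               model_to_json, solve_steady_state)

__all__ = [
    "brute_force_hilbert_basis",
    "random_pointed_cone",
    "generate_fixtures",
]

IntVec = Tuple[int, ...]


def brute_force_hilbert_basis(cone: RationalCone, box: int = 6) -> List[IntVec]:
    """Irreducible monoid elements found by exhaustive box enumeration.

    Enumerates every integer vector with entries in [-box, box], keeps the
    monoid members, and discards any member that is the sum of two nonzero
    members.  Independent of the native algorithm (pure enumeration); only
    meaningful when the true basis lies inside the box, which the callers
    arrange.
    """
    d = cone.ambient_dim
    members = []
    gens = [np.array(g, dtype=np.int64) for g in cone.generators]
    G = np.array(cone.generators, dtype=np.int64)
    for v in itertools.product(range(-box, box + 1), repeat=d):
        if not any(v):
            continue
        if np.all(G @ np.array(v, dtype=np.int64) >= 0):
            members.append(v)
    mset = set(members)
    basis = []
    for v in members:
        reducible = False
        for u in members:
            w = tuple(a - b for a, b in zip(v, u))
            if any(w) and w in mset:
                reducible = True
                break
        if not reducible:
            basis.append(v)
    return sorted(basis)


def random_pointed_cone(rng: np.random.Generator, dim: int,
                        entry_bound: int = 2, max_rows: int = 5) -> RationalCone:
    """Random full-rank integer cone (rows are inequality generators)."""
    while True:
        n_rows = int(rng.integers(dim, max_rows + 1))
        rows = rng.integers(-entry_bound, entry_bound + 1, size=(n_rows, dim))
        rows = [tuple(int(x) for x in r) for r in rows if any(r)]
        if len(rows) >= dim and frac_rank(rows) == dim:
            return RationalCone.from_rows(rows)


_HANDWRITTEN_OUT = """\
2 Hilbert basis elements:

 1 0
 0 1

1 extreme rays:

 1 0
"""


def generate_fixtures(seed: int, outdir) -> Path:
    """Write the deterministic fixture tree; returns the directory path."""
    outdir = Path(outdir)
    (outdir / "cones").mkdir(parents=True, exist_ok=True)
    (outdir / "cascades").mkdir(parents=True, exist_ok=True)
    (outdir / "normaliz").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # (a) cones: the positive orthant plus random pointed cones with
    # brute-forced reference bases
    cones = {"orthant2": RationalCone.from_rows([(1, 0), (0, 1)])}
    for i in range(4):
        dim = 2 + i % 3
        cones[f"random{i}"] = random_pointed_cone(rng, dim)
    refs = {}
    for name, cone in cones.items():
        write_normaliz(cone, outdir / "cones" / f"{name}.in")
        refs[name] = [list(e) for e in brute_force_hilbert_basis(cone)]
    (outdir / "cones" / "reference_bases.json").write_text(
        json.dumps(refs, indent=2, sort_keys=True) + "\n")

    # (b) cascades n=3..9 with known structural g and symmetric rates
    for n in range(3, 10):
        g_true = int(rng.integers(1, 5))
        model = build_end_product_cascade(n, g=g_true)
        ss = solve_steady_state(model, g_true)
        res = float(np.max(np.abs(evaluate_rates(model, ss.concentrations, g_true))))
        assert res < 1e-10
        doc = json.loads(model_to_json(model))
        doc["steady_state"] = [float(x) for x in ss.concentrations]
        (outdir / "cascades" / f"cascade_n{n}.json").write_text(
            json.dumps(doc, indent=2, sort_keys=True) + "\n")

    # (c) hand-written Normaliz output file for the parser
    (outdir / "normaliz" / "example.out").write_text(_HANDWRITTEN_OUT)
    return outdir
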