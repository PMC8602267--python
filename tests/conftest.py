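"""Shared fixtures: small hand-built panels and genotype tables."""

from __future__ import annotations

import pandas as pd
import pytest

from strlink.data_model import (
    GenotypeTable,
    MarkerDef,
    MarkerKind,
    canonical_pair,
    validate_panel,
)


def make_panel(*specs) -> list[MarkerDef]:
    """specs: (name, kind, pos) tuples; STRs get a CA repeat unit."""
    markers = []
    for name, kind, pos in specs:
        k = MarkerKind(kind)
        markers.append(
            MarkerDef(
                name=name,
                chrom="chr15",
                pos=pos,
                kind=k,
                repeat_unit="CA" if k is MarkerKind.STR else None,
            )
        )
    return validate_panel(markers)


def make_gt(panel, calls, groups=None, populations=None) -> GenotypeTable:
    """calls: dict marker -> list of 'a/b' strings or None for missing."""
    marker_map = {m.name: m for m in panel}
    parsed = {}
    n = None
    for name, col in calls.items():
        kind = marker_map[name].kind
        out = []
        for c in col:
            if c is None:
                out.append(None)
            else:
                a, b = c.split("/")
                out.append(canonical_pair(a, b, kind))
        parsed[name] = out
        n = len(out)
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "population": populations or ["pop"] * n,
            "group": groups or [None] * n,
        }
    )
    return GenotypeTable(panel=list(panel), samples=samples, calls=parsed)


@pytest.fixture
def mini_panel():
    return make_panel(("STRX", "STR", 100), ("rsX", "SNP", 200), ("STRY", "STR", 300))


@pytest.fixture
def european_pool():
    from strlink.simulate import build_default_pool

    return build_default_pool("european_like")
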