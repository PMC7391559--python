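"""Readers/writers for the formats the tool touches.

Trees are Newick; everything else is CSV: species environmental profiles
(wide range format or long values format), character matrices over
``{1, 0, ?}``, continuous traits, and reconstruction outputs.  CLI runs
also drop a JSON manifest recording inputs, configuration, seed and
library versions.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binning import (
    BinScheme,
    CharacterMatrix,
    CharacterVector,
    EnvRange,
    SpeciesEnvProfile,
    SYMBOLS,
)
from .continuous import NodeEstimate
from .phylo import Phylogeny, read_newick, write_newick  # re-exported

read_tree = read_newick
write_tree = write_newick


# ---------------------------------------------------------------------------
# species profiles
# ---------------------------------------------------------------------------

def read_profiles(path) -> list[SpeciesEnvProfile]:
    """Read species profiles from CSV.

    Wide/range format: ``species_id, occ_min, occ_max, m_min, m_max``.
    Long/values format: ``species_id, value, in_occupied`` (0/1).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"species_id", "occ_min", "occ_max", "m_min", "m_max"} <= cols:
        return [
            SpeciesEnvProfile(
                species_id=str(r.species_id),
                occupied=EnvRange(float(r.occ_min), float(r.occ_max)),
                accessible=EnvRange(float(r.m_min), float(r.m_max)),
            )
            for r in df.itertuples()
        ]
    if {"species_id", "value", "in_occupied"} <= cols:
        out = []
        for sp, grp in df.groupby("species_id", sort=False):
            acc = grp["value"].to_numpy(dtype=float)
            occ = grp.loc[grp["in_occupied"].astype(int) == 1, "value"].to_numpy(dtype=float)
            if occ.size == 0:
                raise ValueError(f"{sp}: no occupied values in profile file")
            out.append(SpeciesEnvProfile(species_id=str(sp), occupied=occ, accessible=acc))
        return out
    raise ValueError(
        f"unrecognized profile columns {sorted(cols)}; expected range or values layout"
    )


def write_profiles(profiles, path) -> None:
    """Write profiles to CSV (range profiles wide, values profiles long)."""
    profiles = list(profiles)
    modes = {p.mode for p in profiles}
    if modes == {"range"}:
        pd.DataFrame(
            {
                "species_id": [p.species_id for p in profiles],
                "occ_min": [p.occupied.min for p in profiles],
                "occ_max": [p.occupied.max for p in profiles],
                "m_min": [p.accessible.min for p in profiles],
                "m_max": [p.accessible.max for p in profiles],
            }
        ).to_csv(path, index=False)
        return
    if modes == {"values"}:
        rows = []
        for p in profiles:
            occ = set(np.round(p.occupied, 12).tolist())
            for v in p.accessible:
                rows.append((p.species_id, float(v), int(round(float(v), 12) in occ)))
        pd.DataFrame(rows, columns=["species_id", "value", "in_occupied"]).to_csv(
            path, index=False
        )
        return
    raise ValueError("cannot mix range-mode and values-mode profiles in one file")


# ---------------------------------------------------------------------------
# character matrices
# ---------------------------------------------------------------------------

def _parse_bin_label(label: str) -> tuple[float, float]:
    try:
        lo, hi = label.split("_")
        return float(lo), float(hi)
    except ValueError as exc:
        raise ValueError(f"malformed bin label {label!r} (expected 'lower_upper')") from exc


def write_character_matrix(matrix: CharacterMatrix, path) -> None:
    cols = ["species_id"] + matrix.scheme.labels()
    rows = [[r.species_id, *r.states] for r in matrix.rows]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_character_matrix(path, axis_name: str = "env") -> CharacterMatrix:
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] not in ("species_id", "node_id"):
        raise ValueError("first column must be species_id (or node_id)")
    bin_labels = list(df.columns[1:])
    if not bin_labels:
        raise ValueError("matrix has no bin columns")
    bounds = [_parse_bin_label(l) for l in bin_labels]
    widths = {round(hi - lo, 9) for lo, hi in bounds}
    if len(widths) != 1:
        raise ValueError("bins must share one width")
    for (lo1, hi1), (lo2, _) in zip(bounds, bounds[1:]):
        if not np.isclose(hi1, lo2):
            raise ValueError("bins must ascend contiguously")
    if any(lo2 <= lo1 for (lo1, _), (lo2, _) in zip(bounds, bounds[1:])):
        raise ValueError("bins must ascend")
    scheme = BinScheme(
        axis_name=axis_name,
        width=float(widths.pop()),
        lower_edge=bounds[0][0],
        upper_edge=bounds[-1][1],
    )
    rows = []
    for i, rec in enumerate(df.itertuples(index=False)):
        sp = str(rec[0])
        states = tuple(str(s) for s in rec[1:])
        for j, s in enumerate(states):
            if s not in SYMBOLS:
                raise ValueError(
                    f"invalid symbol {s!r} at row {sp!r}, column {bin_labels[j]!r}"
                )
        rows.append(CharacterVector(sp, scheme, states))
    return CharacterMatrix(scheme=scheme, rows=rows)


# ---------------------------------------------------------------------------
# reconstructions, traits, reports
# ---------------------------------------------------------------------------

def write_reconstruction(result, out_dir, prefix: str = "") -> None:
    """Write node-state CSVs (raw + smoothed) and, for ML, marginals."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = result.scheme.labels()
    for which in ("raw", "smoothed"):
        vecs = getattr(result, which)
        rows = [[nid, *vecs[nid].states] for nid in result.node_ids]
        pd.DataFrame(rows, columns=["node_id"] + labels).to_csv(
            out / f"{prefix}{result.method}_nodes_{which}.csv", index=False
        )
    if result.marginals is not None:
        recs = []
        for nid in result.node_ids:
            m = result.marginals[nid]
            for j, lab in enumerate(labels):
                recs.append((nid, lab, *m[j]))
        pd.DataFrame(
            recs, columns=["node_id", "bin", "p_unsuitable", "p_suitable", "p_unknown"]
        ).to_csv(out / f"{prefix}ml_marginals.csv", index=False)


def read_traits(path) -> dict[str, float]:
    df = pd.read_csv(path)
    if not {"species_id", "value"} <= set(df.columns):
        raise ValueError("trait CSV needs columns species_id, value")
    return {str(r.species_id): float(r.value) for r in df.itertuples()}


def write_traits(trait: dict[str, float], path) -> None:
    pd.DataFrame(
        {"species_id": list(trait), "value": list(trait.values())}
    ).to_csv(path, index=False)


def write_node_estimates(estimates: dict[str, NodeEstimate], fitted, path) -> None:
    pd.DataFrame(
        {
            "node_id": list(estimates),
            "estimate": [e.estimate for e in estimates.values()],
            "se": [e.se for e in estimates.values()],
            "model": fitted.model,
            "aic": fitted.aic,
        }
    ).to_csv(path, index=False)


def render_bars(vectors: dict[str, CharacterVector], scheme: BinScheme) -> str:
    """Plain-text bin bars, highest bin on top, one column per species/node."""
    names = list(vectors)
    width = max(len(n) for n in names) if names else 0
    labels = scheme.labels()
    lab_w = max(len(l) for l in labels)
    lines = []
    for j in range(scheme.n_bins - 1, -1, -1):
        cells = " ".join(vectors[n].states[j].center(max(len(n), 1)) for n in names)
        lines.append(f"{labels[j]:>{lab_w}} | {cells}")
    header = " " * (lab_w + 3) + " ".join(n for n in names)
    return "\n".join([header] + lines)


def write_manifest(out_dir, *, command: str, config: dict, seed, inputs: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "nichebar",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
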