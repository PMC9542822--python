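"""Configuration and tabular I/O.

Configs are YAML or JSON; tables are TSV with a one-line header and
optional ``#key: value`` metadata comment lines before it.  All writers'
output round-trips through the corresponding reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .core import FitnessScheme, GeneticArchitecture, Locus, PairInteraction
from .two_deme import TwoDemeConfig
from .zone import ZoneConfig

__all__ = [
    "load_config",
    "save_config",
    "architecture_from_dict",
    "architecture_to_dict",
    "scheme_from_dict",
    "scheme_to_dict",
    "two_deme_config_from_dict",
    "zone_config_from_dict",
    "write_tsv",
    "read_tsv",
]


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(cfg: Mapping, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(dict(cfg), sort_keys=True))


def architecture_from_dict(d: Mapping) -> GeneticArchitecture:
    loci = []
    for rec in d["loci"]:
        kind = rec.get("type", rec.get("kind", "neutral"))
        loci.append(
            Locus(
                id=str(rec["id"]),
                kind=kind,
                s={str(k): float(v) for k, v in (rec.get("s") or {}).items()},
                disfavoured={
                    str(k): int(v) for k, v in (rec.get("disfavoured") or {}).items()
                },
            )
        )
    return GeneticArchitecture(loci, [float(r) for r in d.get("adjacent_r", [])])


def architecture_to_dict(arch: GeneticArchitecture) -> dict:
    loci = []
    for l in arch.loci:
        rec: dict = {"id": l.id, "type": l.kind}
        if l.s:
            rec["s"] = dict(l.s)
        if l.disfavoured:
            rec["disfavoured"] = dict(l.disfavoured)
        loci.append(rec)
    return {"loci": loci, "adjacent_r": list(arch.adjacent_r)}


def scheme_from_dict(d: Mapping | None, architecture: GeneticArchitecture) -> FitnessScheme:
    d = d or {}
    pairs = [
        PairInteraction(str(p["loci"][0]), str(p["loci"][1]), float(p["coefficient"]))
        for p in d.get("pairs", [])
    ]
    return FitnessScheme(architecture, d.get("mode", "multiplicative"), pairs)


def scheme_to_dict(scheme: FitnessScheme) -> dict:
    return {
        "mode": scheme.mode,
        "pairs": [
            {"loci": [p.locus_a, p.locus_b], "coefficient": p.coefficient}
            for p in scheme.pairs
        ],
    }


def two_deme_config_from_dict(d: Mapping) -> TwoDemeConfig:
    return TwoDemeConfig(
        m=float(d["m"]),
        mode=d.get("mode", "unidirectional"),
        max_generations=int(d.get("max_generations", 20000)),
        convergence_tol=float(d.get("convergence_tol", 1e-12)),
        source_env=d.get("source_env", "source"),
        recipient_env=d.get("recipient_env", "recipient"),
    )


def zone_config_from_dict(d: Mapping) -> ZoneConfig:
    barriers = tuple(
        (int(b["interface"]), float(b["permeability"]))
        for b in d.get("physical_barriers", [])
    )
    return ZoneConfig(
        n_demes=int(d.get("n_demes", 200)),
        m=float(d.get("m", 0.5)),
        environment_step=(
            int(d["environment_step"]) if d.get("environment_step") is not None else None
        ),
        physical_barriers=barriers,
        deme_spacing=float(d.get("deme_spacing", 1.0)),
    )


def write_tsv(df: pd.DataFrame, path, metadata: Mapping | None = None) -> None:
    """TSV with '#key: value' metadata comment lines before the header."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"#{key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> tuple[pd.DataFrame, dict]:
    """Read a TSV written by :func:`write_tsv`; returns (frame, metadata)."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition(": ")
            meta[key] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, meta
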