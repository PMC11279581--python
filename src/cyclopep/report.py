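"""End-to-end analysis report over a record collection.

Produces one TSV table per analysis — size classes, ring labels, chain
topology calls, cysteine-pair spacing statistics, composition enrichment,
and (when MIC pairs are supplied) the cyclization-impact summary — plus a
run manifest (versions, seed, thresholds, input digest) sufficient to
reproduce every table bit-exactly.  Counting tables describe whatever
records the caller supplies; absolute counts are corpus-dependent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .io import record_to_dict
from .potency import RELIABILITY_CUTOFF, MICPair, summarize_pairs
from .records import PeptideRecord, size_class
from .rings import classify_record_rings
from .seqstats import composition, disaap_null, enrichment
from .topology import (
    P_HIGH,
    P_LOW,
    S_CUTOFF,
    NotDisulfideCyclic,
    classify_peptide_topology,
)

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Thresholds and knobs for a report run; defaults are the published values."""

    out_dir: Union[str, Path] = "report"
    seed: int = 0
    s_cutoff: float = S_CUTOFF
    p_low: float = P_LOW
    p_high: float = P_HIGH
    reliability_cutoff: int = RELIABILITY_CUTOFF
    pair: tuple[str, str] = ("C", "C")
    max_spacing: int = 10
    n_shuffles: int = 300
    background: Optional[Mapping[str, float]] = None
    strict: bool = False
    group_keys: tuple[str, ...] = ("bond_set", "gram")


def load_background(path: Union[str, Path]) -> dict[str, float]:
    """Read a background composition TSV (columns: symbol, fraction)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["symbol"].astype(str), df["fraction"].astype(float)))


def example_background() -> dict[str, float]:
    """Bundled illustrative average-protein background composition."""
    with resources.as_file(
        resources.files("cyclopep.data") / "example_background.tsv"
    ) as p:
        return load_background(p)


def _digest(records: Sequence[PeptideRecord]) -> str:
    h = hashlib.sha256()
    for rec in records:
        h.update(json.dumps(record_to_dict(rec), sort_keys=True).encode())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_report(
    records: Sequence[PeptideRecord],
    config: RunConfig,
    mic_pairs: Optional[Sequence[MICPair]] = None,
) -> dict:
    """Run every applicable analysis and write one TSV per table.

    Returns the manifest (also written as ``manifest.json``).  Analyses whose
    inputs are missing are skipped with a logged reason; in strict mode a
    skip raises instead.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: list[str] = []
    skipped: dict[str, str] = {}

    # size classes
    size_rows = [
        {
            "id": r.chain.id,
            "length": r.chain.length,
            "size_class": size_class(r.chain.length).value,
            "cyclic": r.is_cyclic,
            "synthesis": r.synthesis.value,
        }
        for r in records
    ]
    _write(pd.DataFrame(size_rows), out / "size_classes.tsv")
    tables.append("size_classes.tsv")

    # ring labels
    ring_rows = []
    for r in records:
        for bond, call in zip(r.bonds, classify_record_rings(r)):
            ring_rows.append(
                {
                    "id": r.chain.id,
                    "kind": bond.kind.value,
                    "linkage": bond.linkage.value,
                    "ring": call.label,
                    "coarse": call.coarse,
                }
            )
    _write(pd.DataFrame(ring_rows,
                        columns=["id", "kind", "linkage", "ring", "coarse"]),
           out / "ring_labels.tsv")
    tables.append("ring_labels.tsv")

    # topology calls
    topo_rows = []
    for r in records:
        try:
            call = classify_peptide_topology(
                r, s_cutoff=config.s_cutoff,
                p_low=config.p_low, p_high=config.p_high,
            )
        except (NotDisulfideCyclic, ValueError):
            continue
        topo_rows.append(
            {
                "id": r.chain.id,
                "k": call.k,
                "class": call.label,
                "s": call.s,
                "p": call.p,
                "crossing_count": call.crossing_count,
                "loop_sizes": ",".join(map(str, call.loop_sizes)),
            }
        )
    _write(pd.DataFrame(topo_rows,
                        columns=["id", "k", "class", "s", "p",
                                 "crossing_count", "loop_sizes"]),
           out / "topology.tsv")
    tables.append("topology.tsv")

    # cysteine-pair spacing distribution with shuffle null
    chains = [r.chain for r in records]
    null = disaap_null(
        chains,
        pair=config.pair,
        max_spacing=config.max_spacing,
        method="shuffle",
        n_shuffles=config.n_shuffles,
        seed=config.seed,
    )
    _write(
        pd.DataFrame(
            {
                "spacing": range(config.max_spacing + 1),
                "observed": null.observed,
                "expected": null.expected,
                "sd": null.sd,
                "z": null.z,
                "p_two_sided": null.p_two_sided,
                "bh_significant": null.bh_significant,
                "ratio": null.ratio,
            }
        ),
        out / "disaap.tsv",
    )
    tables.append("disaap.tsv")

    # composition (and enrichment when a background is configured)
    prof = composition(chains)
    bg = config.background
    comp_rows = []
    table = enrichment(prof, bg, background_id="configured") if bg else None
    for sym in sorted(prof.counts):
        row = {
            "symbol": sym,
            "count": prof.counts[sym],
            "fraction": prof.frequencies[sym],
        }
        if table is not None:
            row["log2_enrichment"] = table.log2_ratio[sym]
            row["floored"] = sym in table.floored
        comp_rows.append(row)
    _write(pd.DataFrame(comp_rows), out / "composition.tsv")
    tables.append("composition.tsv")
    if bg is None:
        skipped["enrichment"] = "no background composition configured"

    # cyclization impact
    if mic_pairs:
        _write(
            summarize_pairs(
                mic_pairs,
                group_keys=config.group_keys,
                reliability_cutoff=config.reliability_cutoff,
            ),
            out / "delta_mic.tsv",
        )
        tables.append("delta_mic.tsv")
    else:
        skipped["delta_mic"] = "no MIC pairs supplied"

    if skipped and config.strict:
        raise ValueError(f"strict mode: skipped analyses: {skipped}")

    manifest = {
        "package": "cyclopep",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "s_cutoff": config.s_cutoff,
            "p_low": config.p_low,
            "p_high": config.p_high,
            "reliability_cutoff": config.reliability_cutoff,
        },
        "pair": list(config.pair),
        "max_spacing": config.max_spacing,
        "n_shuffles": config.n_shuffles,
        "n_records": len(records),
        "n_mic_pairs": len(mic_pairs) if mic_pairs else 0,
        "input_digest_sha256": _digest(records),
        "tables": tables,
        "skipped": skipped,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
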