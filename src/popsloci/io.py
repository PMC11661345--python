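"""File formats and workspace layout.

Variant tables are TSV in the dialect CHR, POS, SNP, A1, A2, FREQ, BETA,
SE, P, N_EFF (1-based positions). Gene models are written both as TSV
(1-based inclusive) and BED (0-based half-open); conversions happen only
here. Reference-panel genotypes are stored as ``.npz`` alongside a
PLINK-style ``.bim`` TSV — a run-time artifact of simulated workspaces.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .finemapping import CredibleSet, Locus
from .ld import BIM_COLUMNS, LDPanel
from .signal_isolation import CojoHit, IndependentSignal, Region
from .sumstats import SUMSTATS_COLUMNS


# --- generic TSV -----------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistics file {path} lacks columns {missing}")
    return df[SUMSTATS_COLUMNS]


def read_genes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    """Gene models as BED: 0-based half-open [start-1, end)."""
    bed = pd.DataFrame(
        {
            "chrom": genes["CHR"],
            "start": genes["START"] - 1,
            "end": genes["END"],
            "name": genes["GENE"],
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", index=False, header=False)


# --- panels ----------------------------------------------------------------

def save_panel(panel: LDPanel, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(str(prefix) + ".npz", genotypes=panel.genotypes)
    write_tsv(panel.variants, str(prefix) + ".bim.tsv")


def load_panel(prefix, ancestry: str) -> LDPanel:
    prefix = Path(prefix)
    geno = np.load(str(prefix) + ".npz")["genotypes"]
    variants = pd.read_csv(str(prefix) + ".bim.tsv", sep="\t")
    return LDPanel(ancestry, geno, variants)


# --- regions / signals -----------------------------------------------------

def save_regions(regions: list[Region], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(
        json.dumps([dataclasses.asdict(r) for r in regions], indent=1)
    )


def load_regions(path) -> list[Region]:
    return [Region(**r) for r in json.loads(Path(path).read_text())]


def save_signals(signals: list[IndependentSignal], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = []
    for sig in signals:
        tsv = f"{sig.signal_id}.cond.tsv"
        write_tsv(sig.conditional_stats, directory / tsv)
        index.append(
            {
                "signal_id": sig.signal_id,
                "lead": sig.lead,
                "region": dataclasses.asdict(sig.region),
                "hits": [dataclasses.asdict(h) for h in sig.hits],
                "conditional_tsv": tsv,
            }
        )
    (directory / "index.json").write_text(json.dumps(index, indent=1))


def load_signals(directory) -> list[IndependentSignal]:
    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    out = []
    for rec in index:
        out.append(
            IndependentSignal(
                region=Region(**rec["region"]),
                lead=rec["lead"],
                hits=[CojoHit(**h) for h in rec["hits"]],
                conditional_stats=pd.read_csv(
                    directory / rec["conditional_tsv"], sep="\t"
                ),
            )
        )
    return out


# --- credible sets / loci --------------------------------------------------

def save_credible_sets(css: list[CredibleSet], path) -> None:
    frames = []
    for cs in css:
        t = cs.table.copy()
        t.insert(0, "SIGNAL", cs.signal_id)
        t.insert(1, "CHR", cs.chrom)
        t["WEIGHTED_CENTER"] = cs.weighted_center
        t["COVERAGE"] = cs.coverage
        frames.append(t)
    write_tsv(pd.concat(frames, ignore_index=True), path)


def load_credible_sets(path) -> list[CredibleSet]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for sid, grp in df.groupby("SIGNAL", sort=False):
        out.append(
            CredibleSet(
                signal_id=sid,
                chrom=int(grp["CHR"].iloc[0]),
                table=grp[["SNP", "POS", "LABF", "PIP", "PIP_CS", "IN_CS"]]
                .reset_index(drop=True),
                coverage=float(grp["COVERAGE"].iloc[0]),
                weighted_center=float(grp["WEIGHTED_CENTER"].iloc[0]),
            )
        )
    return out


def save_loci(loci: list[Locus], json_path, bed_path=None) -> None:
    Path(json_path).parent.mkdir(parents=True, exist_ok=True)
    Path(json_path).write_text(
        json.dumps([dataclasses.asdict(l) for l in loci], indent=1)
    )
    if bed_path is not None:
        bed = pd.DataFrame(
            {
                "chrom": [l.chrom for l in loci],
                "start": [l.start - 1 for l in loci],
                "end": [l.end for l in loci],
                "name": [l.locus_id for l in loci],
            }
        )
        bed.to_csv(bed_path, sep="\t", index=False, header=False)


def load_loci(path) -> list[Locus]:
    return [Locus(**l) for l in json.loads(Path(path).read_text())]


def save_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))
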