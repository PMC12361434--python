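"""Reading and writing the plain-text formats used by the pipeline.

bedGraph (4-column, no header) carries binned count or signal tracks;
BED3/BED6 carries regions, genes and peak calls; TSV carries sample
sheets and result tables; JSON carries the simulation ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Genome, Region
from .simulate import SimulatedDataset, TruthSpec
from .stats import SignifResult
from .track import BinnedTrack

__all__ = [
    "SampleSheetEntry",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "write_bedgraph",
    "read_bedgraph",
    "read_bed",
    "write_bed",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_results",
    "write_truth",
    "read_truth",
    "write_dataset",
    "write_wide_tsv",
]


@dataclass(frozen=True)
class SampleSheetEntry:
    clone: str
    allele: str
    replicate: int
    fraction: str
    path: str

    def __post_init__(self) -> None:
        if self.fraction not in ("early", "late"):
            raise ValueError("fraction must be 'early' or 'late'")


def read_chrom_sizes(path, bin_size: int = 50_000) -> Genome:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return Genome(
        names=tuple(df["chrom"].astype(str)),
        lengths=tuple(int(x) for x in df["length"]),
        bin_size=bin_size,
    )


def write_chrom_sizes(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(genome.names, genome.lengths):
            fh.write(f"{name}\t{length}\n")


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write non-missing bins as chrom/start/end/value rows."""
    with open(path, "w") as fh:
        b = track.bin_size
        for chrom in track.chroms:
            vals = track.data[chrom]
            for i in np.flatnonzero(np.isfinite(vals)):
                fh.write(f"{chrom}\t{i * b}\t{(i + 1) * b}\t{vals[i]:.6g}\n")


def read_bedgraph(
    path,
    genome: Genome,
    bin_size: int | None = None,
    stage: str = "counts",
    meta: dict | None = None,
) -> BinnedTrack:
    """Load a bedGraph onto the bin grid; absent bins become missing."""
    track = BinnedTrack(genome, stage=stage, bin_size=bin_size, meta=meta)
    b = track.bin_size
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    for chrom, sub in df.groupby("chrom"):
        chrom = str(chrom)
        if chrom not in track.data:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
        idx = sub["start"].to_numpy() // b
        if np.any(sub["start"].to_numpy() % b) or np.any(
            sub["end"].to_numpy() - sub["start"].to_numpy() != b
        ):
            raise ValueError(f"{path}: intervals are not aligned {b}-bp bins")
        n = track.data[chrom].size
        keep = idx < n  # trailing partial-bin rows are dropped by the grid
        track.data[chrom][idx[keep]] = sub["value"].to_numpy()[keep]
    return track


def read_bed(path) -> list[Region]:
    """Read BED3/BED6; the 4th column, when present, becomes the label."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            label = parts[3] if len(parts) > 3 else None
            regions.append(Region(parts[0], int(parts[1]), int(parts[2]), label))
    return regions


def write_bed(regions: list[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = r.label if r.label is not None else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


def read_sample_sheet(path) -> list[SampleSheetEntry]:
    df = pd.read_csv(path, sep="\t")
    required = {"clone", "allele", "replicate", "fraction", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    entries = [
        SampleSheetEntry(
            clone=str(row.clone), allele=str(row.allele),
            replicate=int(row.replicate), fraction=str(row.fraction),
            path=str(row.path),
        )
        for row in df.itertuples()
    ]
    _check_sheet(entries)
    return entries


def _check_sheet(entries: list[SampleSheetEntry]) -> None:
    seen: dict[tuple, set] = {}
    for e in entries:
        key = (e.clone, e.allele, e.replicate)
        fracs = seen.setdefault(key, set())
        if e.fraction in fracs:
            raise ValueError(f"duplicate {e.fraction} entry for {key}")
        fracs.add(e.fraction)
    for key, fracs in seen.items():
        if fracs != {"early", "late"}:
            raise ValueError(f"{key}: needs exactly one early and one late entry")


def write_sample_sheet(entries: list[SampleSheetEntry], path) -> None:
    pd.DataFrame([e.__dict__ for e in entries]).to_csv(path, sep="\t", index=False)


def write_results(results: list[SignifResult], path, clone_ids=None) -> None:
    rows = []
    for i, r in enumerate(results):
        rows.append(
            {
                "clone": (clone_ids[i] if clone_ids else f"clone{i + 1}"),
                "query": str(r.query),
                "kind": r.kind,
                "delta_area": r.delta_area,
                "abs_delta_area": r.abs_delta_area,
                "pvalue": r.pvalue,
                "n_random": r.n_random,
                "significant": r.significant,
                "control_mode": r.control_mode,
                "seed": r.seed,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth(truth: TruthSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)


def read_truth(path) -> TruthSpec:
    with open(path) as fh:
        return TruthSpec.from_dict(json.load(fh))


def write_wide_tsv(tracks: dict, path) -> None:
    """Wide bin x sample table of track values (missing as empty)."""
    first = next(iter(tracks.values()))
    b = first.bin_size
    rows = {"chrom": [], "start": [], "end": []}
    for chrom in first.chroms:
        n = first.data[chrom].size
        rows["chrom"].extend([chrom] * n)
        rows["start"].extend(range(0, n * b, b))
        rows["end"].extend(range(b, (n + 1) * b, b))
    df = pd.DataFrame(rows)
    for key, track in tracks.items():
        name = key if isinstance(key, str) else "_".join(str(k) for k in key)
        df[name] = track.flatten()
    df.to_csv(path, sep="\t", index=False, na_rep="")


def write_dataset(ds: SimulatedDataset, outdir) -> Path:
    """Write a simulated dataset: bedGraphs, sample sheet, truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_chrom_sizes(ds.genome, outdir / "chrom.sizes")
    entries = []
    for (allele, rep, frac), track in ds.counts.items():
        fname = f"counts_{allele}_rep{rep}_{frac}.bedgraph"
        write_bedgraph(track, outdir / fname)
        entries.append(
            SampleSheetEntry(
                clone="sim", allele=allele, replicate=rep, fraction=frac,
                path=fname,
            )
        )
    write_sample_sheet(entries, outdir / "samples.tsv")
    for allele, track in ds.bru.items():
        write_bedgraph(track, outdir / f"bru_{allele}.bedgraph")
    write_truth(ds.truth, outdir / "truth.json")
    return outdir
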