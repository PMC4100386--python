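"""Plain-text readers and writers for the pipeline's artefacts.

Internal coordinates are 1-based inclusive throughout; BED output is
converted to 0-based half-open (start-1, end). State matrices travel as
TSV with one header line and digit states; recombination maps use the
HapMap genetic-map text layout (position, rate in cM/Mb, cumulative cM)
with one file per chromosome, plus a hotspot BED.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import CNVRecord, HMMParams, RecombMap, SNPMap, StateMatrix


# -- SNP map ----------------------------------------------------------------

def write_snp_map(snp_map: SNPMap, path: str | os.PathLike) -> None:
    snp_map.table.to_csv(path, sep="\t", index=False)


def read_snp_map(path: str | os.PathLike) -> SNPMap:
    return SNPMap(pd.read_csv(path, sep="\t", dtype={"snp_id": str}))


# -- state matrices ---------------------------------------------------------

def write_state_matrix(states: StateMatrix, snp_map: SNPMap, path: str | os.PathLike) -> None:
    """TSV: individual_id, label, then one digit column per SNP."""
    cols = ["individual_id", "label", *snp_map.snp_ids]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i in range(states.n_individuals):
            row = states.states[i]
            fh.write(
                f"{states.individual_ids[i]}\t{states.labels[i]}\t"
                + "\t".join(map(str, row))
                + "\n"
            )


def read_state_matrix(path: str | os.PathLike, cohort_id: str = "cohort") -> StateMatrix:
    df = pd.read_csv(path, sep="\t")
    ids = df["individual_id"].to_numpy(dtype=object)
    labels = df["label"].to_numpy(dtype=object)
    states = df.drop(columns=["individual_id", "label"]).to_numpy(dtype=np.int8)
    return StateMatrix(states=states, labels=labels, cohort_id=cohort_id, individual_ids=ids)


def write_intensity_matrix(signal, labels, individual_ids, snp_map: SNPMap, path: str | os.PathLike) -> None:
    """TSV twin of the state-matrix layout with float intensities."""
    cols = ["individual_id", "label", *snp_map.snp_ids]
    df = pd.DataFrame(np.asarray(signal), columns=list(snp_map.snp_ids))
    df.insert(0, "label", labels)
    df.insert(0, "individual_id", individual_ids)
    df.to_csv(path, sep="\t", index=False, columns=cols)


def read_intensity_matrix(path: str | os.PathLike):
    """Returns (signal ndarray, labels, individual_ids)."""
    df = pd.read_csv(path, sep="\t")
    ids = df["individual_id"].to_numpy(dtype=object)
    labels = df["label"].to_numpy(dtype=object)
    signal = df.drop(columns=["individual_id", "label"]).to_numpy(dtype=float)
    return signal, labels, ids


# -- recombination maps -----------------------------------------------------

def write_genetic_maps(recomb_map: RecombMap, out_dir: str | os.PathLike) -> list[Path]:
    """One HapMap-layout genetic-map file per chromosome.

    Rows are ``position  rate(cM/Mb)  cumulative_cM``: the rate applies
    from this position up to the next row's position; the final row
    closes the last interval with rate 0.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for chrom, sub in recomb_map.intervals.groupby("chrom"):
        path = out_dir / f"genetic_map_chr{chrom}.txt"
        cum = 0.0
        with open(path, "w") as fh:
            fh.write("position\tCOMBINED_rate(cM/Mb)\tGenetic_Map(cM)\n")
            for _, r in sub.iterrows():
                fh.write(f"{int(r['start'])}\t{r['rate']:.6f}\t{cum:.8f}\n")
                cum += r["rate"] * (r["end"] - r["start"] + 1) / 1e6
            last = sub.iloc[-1]
            fh.write(f"{int(last['end']) + 1}\t{0.0:.6f}\t{cum:.8f}\n")
        paths.append(path)
    return paths


def read_genetic_maps(paths: list[str | os.PathLike], hotspot_bed: str | os.PathLike | None = None) -> RecombMap:
    """Rebuild a RecombMap from per-chromosome genetic-map files.

    File names must contain ``chr<N>``; a trailing zero-rate row closes
    the final interval and is not itself an interval.
    """
    rows = []
    for path in paths:
        name = Path(path).name
        chrom = int(name.split("chr")[1].split(".")[0].split("_")[0])
        df = pd.read_csv(path, sep="\t")
        pos = df.iloc[:, 0].to_numpy(dtype=np.int64)
        rate = df.iloc[:, 1].to_numpy(dtype=float)
        for i in range(len(df) - 1):
            rows.append((chrom, int(pos[i]), int(pos[i + 1]) - 1, float(rate[i])))
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "rate"])
    intervals = intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
    hotspots = (
        read_bed(hotspot_bed)
        if hotspot_bed is not None
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    return RecombMap(intervals=intervals, hotspots=hotspots)


def write_bed(intervals: pd.DataFrame, path: str | os.PathLike, name_col: str | None = None) -> None:
    """Write 1-based closed (chrom, start, end[, name]) intervals as BED
    (0-based half-open: start-1, end)."""
    with open(path, "w") as fh:
        for _, r in intervals.iterrows():
            line = f"chr{int(r['chrom'])}\t{int(r['start']) - 1}\t{int(r['end'])}"
            if name_col is not None:
                line += f"\t{r[name_col]}"
            fh.write(line + "\n")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read BED into 1-based closed (chrom, start, end) intervals."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom = int(parts[0].removeprefix("chr"))
            rows.append((chrom, int(parts[1]) + 1, int(parts[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)


# -- HMM parameters ---------------------------------------------------------

def write_hmm_params(params: HMMParams, path: str | os.PathLike) -> None:
    payload = {
        "initial": [float(x) for x in params.initial],
        "transition": [[float(x) for x in row] for row in params.transition],
        "means": [float(x) for x in params.means],
        "sds": [float(x) for x in params.sds],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_hmm_params(path: str | os.PathLike) -> HMMParams:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return HMMParams(
        initial=np.array(payload["initial"], dtype=float),
        transition=np.array(payload["transition"], dtype=float),
        means=np.array(payload["means"], dtype=float),
        sds=np.array(payload["sds"], dtype=float),
    )


# -- CNV records ------------------------------------------------------------

def cnv_records_to_frame(records: list[CNVRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dataset": r.dataset,
                "chrom": r.chrom,
                "band": r.band,
                "start_pos": r.start_pos,
                "end_pos": r.end_pos,
                "size_kb": r.size_kb,
                "cnv_type": r.cnv_type,
                "members": ",".join(r.member_snp_ids),
            }
            for r in records
        ],
        columns=["dataset", "chrom", "band", "start_pos", "end_pos", "size_kb", "cnv_type", "members"],
    )


def write_cnv_records(records: list[CNVRecord], path: str | os.PathLike) -> None:
    cnv_records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_cnv_records(path: str | os.PathLike) -> list[CNVRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        CNVRecord(
            dataset=str(r["dataset"]),
            chrom=int(r["chrom"]),
            start_pos=int(r["start_pos"]),
            end_pos=int(r["end_pos"]),
            cnv_type=str(r["cnv_type"]),
            member_snp_ids=tuple(str(r["members"]).split(",")) if r["members"] else (),
            band=str(r["band"]),
        )
        for _, r in df.iterrows()
    ]


def write_cnv_bed(records: list[CNVRecord], path: str | os.PathLike) -> None:
    df = cnv_records_to_frame(records).rename(columns={"start_pos": "start", "end_pos": "end"})
    write_bed(df, path, name_col="cnv_type")


# -- gene annotation --------------------------------------------------------

def read_gene_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Genes from a simple TSV (chrom, start, end, name; 1-based closed)
    or BED (named intervals, 0-based half-open)."""
    path = Path(path)
    if path.suffix == ".bed":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.rstrip("\n").split("\t")
                rows.append((int(parts[0].removeprefix("chr")), int(parts[1]) + 1, int(parts[2]), parts[3]))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    else:
        df = pd.read_csv(path, sep="\t")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_manifest(entries: dict, path: str | os.PathLike) -> None:
    """Key/value run manifest, one ``key = value`` line each."""
    with open(path, "w") as fh:
        for k, v in entries.items():
            fh.write(f"{k} = {v}\n")
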