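"""Readers and writers for the TSV/JSON interchange formats.

The AF and SNV tables are tab-separated with columns ``chrom``, ``pos``,
``arm`` followed by one column per sample (values in [0, 1]; empty cells are
missing).  The sample sheet lists ``sample`` and ``role`` (``normal`` or
``tumor``); exactly one normal/precursor sample is required.  Coordinates
are 1-based.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cstep import SampleEstimate
from .model import AlleleCombination, MeasurementBundle
from .tstep import Tree

logger = logging.getLogger("laftree")

_META_COLS = ["chrom", "pos", "arm"]


def _read_table(path: str | Path, samples: list[str]) -> tuple[list, np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "arm": str})
    missing = [c for c in _META_COLS + samples if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=_META_COLS)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicated position {row['chrom']}{row['arm']}:{row['pos']}"
        )
    # natural chromosome order: 1..22 numerically, then X/Y/... as strings
    chrom_key = df["chrom"].map(
        lambda c: (0, int(c), "") if str(c).isdigit() else (1, 0, str(c))
    )
    order = (
        df.assign(_ck=chrom_key)
        .sort_values(["_ck", "arm", "pos"], kind="stable")
        .index
    )
    if not (order.values == df.index.values).all():
        logger.warning("%s: rows were not genome-sorted; sorting", path)
        df = df.loc[order].reset_index(drop=True)
    values = df[samples].to_numpy(dtype=float)
    out_of_range = (values < 0) | (values > 1)
    if np.isfinite(values)[out_of_range & np.isfinite(values)].any():
        logger.warning("%s: AF values outside [0, 1] clipped", path)
        values = np.clip(values, 0.0, 1.0)
    positions = [
        (str(r.chrom), str(r.arm), int(r.pos)) for r in df.itertuples(index=False)
    ]
    return positions, values


def read_bundle(
    af_path: str | Path, snv_path: str | Path | None, samples_path: str | Path
) -> MeasurementBundle:
    """Load a measurement bundle from its three TSV files."""
    sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
    if not {"sample", "role"} <= set(sheet.columns):
        raise ValueError(f"{samples_path}: needs columns 'sample' and 'role'")
    samples = sheet["sample"].tolist()
    normals = sheet.index[sheet["role"].str.lower().isin(["normal", "precursor"])]
    if len(normals) != 1:
        raise ValueError("exactly one normal/precursor sample is required")
    positions, af = _read_table(af_path, samples)
    if snv_path is not None:
        snv_positions, snv_af = _read_table(snv_path, samples)
    else:
        snv_positions, snv_af = [], np.zeros((0, len(samples)))
    return MeasurementBundle(
        af=af,
        positions=positions,
        snv_af=snv_af,
        snv_positions=snv_positions,
        sample_names=samples,
        normal_index=int(normals[0]),
    )


def _meta_frame(positions) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p[0] for p in positions],
            "pos": [p[2] for p in positions],
            "arm": [p[1] for p in positions],
        }
    )


def write_bundle(bundle: MeasurementBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write af.tsv, snv.tsv and samples.tsv; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    af_df = _meta_frame(bundle.positions)
    for j, name in enumerate(bundle.sample_names):
        af_df[name] = bundle.af[:, j]
    af_path = out / "af.tsv"
    af_df.to_csv(af_path, sep="\t", index=False)
    snv_df = _meta_frame(bundle.snv_positions)
    for j, name in enumerate(bundle.sample_names):
        snv_df[name] = bundle.snv_af[:, j] if bundle.snv_af.size else []
    snv_path = out / "snv.tsv"
    snv_df.to_csv(snv_path, sep="\t", index=False)
    sheet = pd.DataFrame(
        {
            "sample": bundle.sample_names,
            "role": [
                "normal" if j == bundle.normal_index else "tumor"
                for j in range(bundle.n_samples)
            ],
        }
    )
    samples_path = out / "samples.tsv"
    sheet.to_csv(samples_path, sep="\t", index=False)
    return {"af": af_path, "snv": snv_path, "samples": samples_path}


def tree_to_dot(tree: Tree) -> str:
    lines = ["digraph lineage {", "  rankdir=TB;"]
    for node in tree.nodes:
        shape = "doublecircle" if node == tree.root else "ellipse"
        lines.append(f'  "{node}" [shape={shape}];')
    for p, c in sorted(tree.edges()):
        w = tree.edge_weights.get((p, c), 0.0)
        lines.append(f'  "{p}" -> "{c}" [label="{w:g}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_results(
    estimates: dict[str, SampleEstimate],
    tree: Tree,
    out_dir: str | Path,
    bundle: MeasurementBundle,
    candidates: list[Tree] | None = None,
    run_info: dict | None = None,
) -> None:
    """Write C.tsv, A.tsv, mu.tsv, tree.json/.dot and candidate trees."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = bundle.sample_names
    meta = _meta_frame(bundle.positions)
    c_df = meta.copy()
    a_df = meta.copy()
    for name in names:
        est = estimates[name]
        c_df[name] = est.copy_numbers
        a_df[name] = [str(al) if al.copy_number else "-" for al in est.alleles.alleles]
    c_df.to_csv(out / "C.tsv", sep="\t", index=False)
    a_df.to_csv(out / "A.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"sample": names, "mu": [estimates[n].mu for n in names]}
    ).to_csv(out / "mu.tsv", sep="\t", index=False)
    (out / "tree.json").write_text(json.dumps(tree.to_dict(), indent=2) + "\n")
    (out / "tree.dot").write_text(tree_to_dot(tree))
    if candidates:
        cand_dir = out / "candidates"
        cand_dir.mkdir(exist_ok=True)
        for k, cand in enumerate(candidates[:10], start=1):
            (cand_dir / f"tree_{k:02d}.json").write_text(
                json.dumps(cand.to_dict(), indent=2) + "\n"
            )
    if run_info is not None:
        (out / "run.json").write_text(json.dumps(run_info, indent=2) + "\n")


def read_copy_table(path: str | Path, samples: list[str]) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "arm": str})
    return df[samples].to_numpy(dtype=int)


def read_allele_table(path: str | Path, samples: list[str]):
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        [AlleleCombination.from_string(v) for v in row]
        for row in df[samples].itertuples(index=False)
    ]


def read_tree_json(path: str | Path) -> Tree:
    doc = json.loads(Path(path).read_text())
    weights = {
        (e["parent"], e["child"]): float(e["weight"]) for e in doc["edges"]
    }
    return Tree(parent=dict(doc["parent"]), root=doc["root"], edge_weights=weights)
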