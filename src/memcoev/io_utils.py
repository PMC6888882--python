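"""Plain-text serialization shared by the library and the CLI.

Formats: TSV tables (events, per-site counts, conditional profiles,
avalanche partitions), JSON for fit summaries, a FASTA-like container for
binary alignments (header carries identity and seed), and flat key=value
configuration files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment_stats import BinaryAlignment, ConditionalProfile, NegBinomFit
from .avalanche import AvalanchePartition, MutationMatrix
from .divergence_sim import DivergenceResult, SubstitutionEvent
from .errors import InvalidInputError


# -- binary alignments (FASTA-like, 0/1 strings) ----------------------------

def write_binary_alignments(alignments: Iterable, path) -> None:
    lines = []
    for idx, a in enumerate(alignments):
        if isinstance(a, BinaryAlignment):
            symbols, identity, source = a.symbols, a.identity, a.source
        else:
            symbols = np.asarray(a, dtype=np.uint8)
            identity, source = 1.0 - symbols.mean(), ""
        tag = source or f"aln{idx}"
        lines.append(f">{tag} identity={identity:.6f}")
        lines.append("".join(str(int(s)) for s in symbols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_binary_alignments(path) -> list[BinaryAlignment]:
    out = []
    header, symbols = None, []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith(">"):
            if header is not None:
                out.append(_finish_alignment(header, symbols, path))
            header, symbols = ln[1:], []
        else:
            if header is None:
                raise InvalidInputError(f"{path}: sequence data before first header")
            symbols.append(ln)
    if header is not None:
        out.append(_finish_alignment(header, symbols, path))
    if not out:
        raise InvalidInputError(f"{path}: no alignments found")
    return out


def _finish_alignment(header: str, chunks: list[str], path) -> BinaryAlignment:
    s = "".join(chunks)
    if not s or set(s) - {"0", "1"}:
        raise InvalidInputError(f"{path}: alignment body must be a 0/1 string")
    arr = np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")
    fields = dict(f.split("=", 1) for f in header.split()[1:] if "=" in f)
    identity = float(fields.get("identity", 1.0 - arr.mean()))
    return BinaryAlignment(arr, identity=identity, source=header.split()[0])


# -- divergence outputs -----------------------------------------------------

def events_frame(events: Sequence[SubstitutionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.branch, e.site, e.time) for e in events],
        columns=["branch", "site", "time"],
    )


def write_divergence_result(result: DivergenceResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events_frame(result.events).to_csv(out / "events.tsv", sep="\t", index=False)
    pd.DataFrame({
        "site": np.arange(result.counts_a.shape[0]),
        "count_a": result.counts_a,
        "count_b": result.counts_b,
        "mutated": result.mutated.astype(int),
    }).to_csv(out / "counts.tsv", sep="\t", index=False)
    start, length = result.window
    aln = BinaryAlignment(result.alignment, identity=result.identity,
                          source=f"window_{start}_{length}")
    write_binary_alignments([aln], out / "alignment.txt")
    summary = {
        "identity": result.identity,
        "reached_target": result.reached_target,
        "n_steps": result.n_steps,
        "multi_substitution_steps": result.multi_substitution_steps,
        "multi_substitution_fraction": result.multi_substitution_fraction,
        "window_start": start,
        "window_length": length,
        "seed": result.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")


# -- profiles and fits ------------------------------------------------------

def write_profile(profile: ConditionalProfile, path) -> None:
    pd.DataFrame({
        "d": profile.d, "N1": profile.n1, "N0": profile.n0, "P": profile.p,
    }).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_profile(path, trim: int = 5) -> ConditionalProfile:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("d", "N1", "N0"):
        if col not in df.columns:
            raise InvalidInputError(f"{path}: missing column {col}")
    return ConditionalProfile(
        d=df["d"].to_numpy(dtype=np.int64),
        n1=df["N1"].to_numpy(dtype=np.int64),
        n0=df["N0"].to_numpy(dtype=np.int64),
        trim=trim,
    )


def write_fit(fit: NegBinomFit, path) -> None:
    Path(path).write_text(json.dumps({
        "alpha": fit.alpha, "mean_k": fit.mean_k,
        "rms_residual": fit.rms_residual, "n_sites": fit.n_sites,
    }, indent=2) + "\n")


# -- avalanches -------------------------------------------------------------

def write_partition(partition: AvalanchePartition, path) -> None:
    cls = partition.classification()
    pd.DataFrame({
        "site": partition.events[:, 0],
        "time": partition.events[:, 1],
        "component": partition.labels,
        "size": partition.sizes[partition.labels],
        "size_class": cls,
    }).to_csv(path, sep="\t", index=False)


def read_partition(path) -> AvalanchePartition:
    df = pd.read_csv(path, sep="\t")
    events = df[["site", "time"]].to_numpy(dtype=np.int64)
    labels = df["component"].to_numpy(dtype=np.int64)
    sizes = np.bincount(labels) if labels.size else np.zeros(0, dtype=int)
    return AvalanchePartition(events=events, labels=labels, sizes=sizes)


def write_mutation_matrix(m: MutationMatrix, path) -> None:
    np.savetxt(path, m.values, fmt="%d", delimiter="\t")


def read_mutation_matrix(path) -> MutationMatrix:
    return MutationMatrix(np.loadtxt(path, delimiter="\t", dtype=int, ndmin=2))


# -- flat key=value config --------------------------------------------------

def parse_config(path) -> dict[str, str]:
    """Read a flat ``key = value`` file; '#' starts a comment."""
    out: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        if "=" not in ln:
            raise InvalidInputError(f"{path}: malformed config line {ln!r}")
        key, value = ln.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_config(config: dict, path) -> None:
    Path(path).write_text(
        "\n".join(f"{k} = {v}" for k, v in config.items()) + "\n"
    )
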