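"""File formats: genomic signal tracks, BED, contact containers, trajectories.

Signal tracks (IPLS, MRT, ...) are bedGraph or fixedStep wiggle at 1 kb;
intervals are 0-based half-open in bedGraph and 1-based in wiggle.  Contact
maps are written as a multi-resolution HDF5 container following the cooler
schema (``resolutions/<res>`` groups with chroms/bins/pixels/indexes tables,
symmetric-upper storage), readable by cooler-ecosystem tools.  Trajectories
go to .npz archives with a JSON metadata block.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contacts import ContactMap
from .genome import GenomeSpec
from .kinetics import IPLSTrack
from .world import Trajectory


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

def write_signal(spec: GenomeSpec, values, path, fmt: str = "bedgraph",
                 name: str = "signal") -> None:
    """Write a per-1 kb signal as bedGraph (zero bins omitted) or wiggle."""
    values = np.asarray(values, dtype=float)
    if values.shape != (spec.n_monomers,):
        raise ValueError("signal length does not match the genome")
    path = Path(path)
    with open(path, "w") as fh:
        if fmt == "bedgraph":
            fh.write(f"# {name}; 1 kb bins, 0-based half-open\n")
            for idx, chrom in enumerate(spec.chroms):
                mask = spec.bin_chrom == idx
                vals = values[mask]
                starts = spec.bin_start_kb[mask]
                nz = vals != 0
                for s, v in zip(starts[nz], vals[nz]):
                    fh.write(f"{chrom}\t{s * 1000}\t{(s + 1) * 1000}\t{v:g}\n")
        elif fmt == "wiggle":
            for idx, chrom in enumerate(spec.chroms):
                mask = spec.bin_chrom == idx
                fh.write(f"fixedStep chrom={chrom} start=1 step=1000 "
                         f"span=1000\n")
                for v in values[mask]:
                    fh.write(f"{v:g}\n")
        else:
            raise ValueError(f"unknown track format {fmt!r}")


def read_signal(path, spec: GenomeSpec) -> np.ndarray:
    """Read a bedGraph or fixedStep wiggle into per-1 kb values."""
    path = Path(path)
    values = np.zeros(spec.n_monomers)
    seen = np.zeros(spec.n_monomers, bool)
    chrom_index = {c: i for i, c in enumerate(spec.chroms)}
    offsets = {}
    for idx, chrom in enumerate(spec.chroms):
        offsets[chrom] = np.flatnonzero(spec.bin_chrom == idx)

    def put(chrom, kb, v):
        if chrom not in chrom_index:
            raise ValueError(f"unknown chromosome {chrom!r}")
        bins = offsets[chrom]
        if kb < 0 or kb >= len(bins):
            raise ValueError(f"{chrom}:{kb} kb outside the genome")
        b = bins[kb]
        if seen[b]:
            raise ValueError(f"overlapping intervals at {chrom}:{kb} kb")
        seen[b] = True
        values[b] = v

    with open(path) as fh:
        mode = None
        chrom = None
        kb = 0
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                start = int(fields.get("start", 1)) - 1
                step = int(fields.get("step", 1000))
                span = int(fields.get("span", step))
                if start % 1000 or step != 1000 or span != 1000:
                    raise ValueError("wiggle track is not at 1 kb binning")
                kb = start // 1000
                mode = "wig"
                continue
            if mode == "wig" and len(line.split()) == 1:
                put(chrom, kb, float(line))
                kb += 1
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed bedGraph line: {line!r}")
            c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if s % 1000 or (e - s) % 1000:
                raise ValueError("bedGraph intervals must tile 1 kb bins")
            for k in range(s // 1000, e // 1000):
                put(c, k, v)
    return values


def read_track(path, spec: GenomeSpec) -> IPLSTrack:
    return IPLSTrack(spec, read_signal(path, spec))


def write_track(track: IPLSTrack, path, fmt: str = "bedgraph") -> None:
    write_signal(track.spec, track.values, path, fmt=fmt, name="IPLS")


def write_bed(spec: GenomeSpec, bins, path, names=None) -> None:
    """Write global bins as BED intervals (0-based, half-open, 1 kb)."""
    with open(path, "w") as fh:
        for i, b in enumerate(np.asarray(bins, dtype=int)):
            chrom = spec.chroms[int(spec.bin_chrom[b])]
            s = int(spec.bin_start_kb[b]) * 1000
            nm = names[i] if names is not None else f"{chrom}:{s}"
            fh.write(f"{chrom}\t{s}\t{s + 1000}\t{nm}\n")


def read_bed_bins(path, spec: GenomeSpec) -> np.ndarray:
    """Map BED intervals to global 1 kb bins (midpoint rule)."""
    out = []
    chrom_index = {c: i for i, c in enumerate(spec.chroms)}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split()
        chrom, s, e = parts[0], int(parts[1]), int(parts[2])
        if chrom not in chrom_index:
            raise ValueError(f"unknown chromosome {chrom!r}")
        mid_kb = (s + e) // 2 // 1000
        bins = np.flatnonzero(spec.bin_chrom == chrom_index[chrom])
        if mid_kb >= len(bins):
            raise ValueError(f"interval {line!r} outside the genome")
        out.append(bins[mid_kb])
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# contact containers (cooler-schema HDF5)
# ---------------------------------------------------------------------------

_MCOOL_RESOLUTIONS = (1, 2, 4, 8, 16)


def _write_cooler_group(grp, cmap: ContactMap) -> None:
    bins = cmap.bins
    chroms = list(dict.fromkeys(bins["chrom"]))
    lengths = [int(bins.loc[bins["chrom"] == c, "end"].max()) for c in chroms]
    cid = {c: i for i, c in enumerate(chroms)}
    bin_chrom = bins["chrom"].map(cid).to_numpy(np.int32)
    upper = sp.triu(cmap.mat.tocoo())
    order = np.lexsort((upper.col, upper.row))
    b1, b2, cnt = upper.row[order], upper.col[order], upper.data[order]

    g = grp.create_group("chroms")
    g.create_dataset("name", data=np.array(chroms, dtype="S32"))
    g.create_dataset("length", data=np.array(lengths, dtype=np.int64))
    g = grp.create_group("bins")
    g.create_dataset("chrom", data=bin_chrom)
    g.create_dataset("start", data=bins["start"].to_numpy(np.int64))
    g.create_dataset("end", data=bins["end"].to_numpy(np.int64))
    w = (cmap.weights if cmap.weights is not None
         else np.ones(cmap.n_bins))
    g.create_dataset("weight", data=w.astype(float))
    g = grp.create_group("pixels")
    g.create_dataset("bin1_id", data=b1.astype(np.int64))
    g.create_dataset("bin2_id", data=b2.astype(np.int64))
    g.create_dataset("count", data=cnt.astype(float))
    g = grp.create_group("indexes")
    chrom_offset = np.searchsorted(bin_chrom, np.arange(len(chroms) + 1))
    bin1_offset = np.searchsorted(b1, np.arange(cmap.n_bins + 1))
    g.create_dataset("chrom_offset", data=chrom_offset.astype(np.int64))
    g.create_dataset("bin1_offset", data=bin1_offset.astype(np.int64))
    grp.attrs["format"] = "HDF5::Cooler"
    grp.attrs["format-version"] = 3
    grp.attrs["bin-type"] = "fixed"
    grp.attrs["bin-size"] = cmap.resolution_kb * 1000
    grp.attrs["storage-mode"] = "symmetric-upper"
    grp.attrs["nbins"] = cmap.n_bins
    grp.attrs["nchroms"] = len(chroms)
    grp.attrs["nnz"] = len(cnt)


def export_contacts(cmap: ContactMap, path,
                    resolutions=_MCOOL_RESOLUTIONS) -> None:
    """Write a multi-resolution contact container (cooler .mcool schema).

    The native map provides the base layer; coarser layers sum its counts."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "HDF5::MCOOL"
        fh.attrs["format-version"] = 2
        root = fh.create_group("resolutions")
        base = cmap.resolution_kb
        for res in resolutions:
            if res < base or res % base:
                continue
            layer = cmap.coarsen(res // base)
            _write_cooler_group(root.create_group(str(res * 1000)), layer)


def read_contacts(path, resolution_kb: int = 1) -> ContactMap:
    """Read one resolution layer of an exported contact container."""
    with h5py.File(path, "r") as fh:
        grp = fh[f"resolutions/{resolution_kb * 1000}"]
        names = [n.decode() for n in grp["chroms/name"][:]]
        bins = pd.DataFrame({
            "chrom": [names[i] for i in grp["bins/chrom"][:]],
            "start": grp["bins/start"][:],
            "end": grp["bins/end"][:],
        })
        w = grp["bins/weight"][:]
        b1 = grp["pixels/bin1_id"][:]
        b2 = grp["pixels/bin2_id"][:]
        cnt = grp["pixels/count"][:]
    n = len(bins)
    upper = sp.coo_matrix((cnt, (b1, b2)), shape=(n, n)).tocsr()
    diag = sp.diags(upper.diagonal())
    mat = upper + upper.T - diag
    weights = None if np.allclose(w, 1.0) else w
    return ContactMap(bins, mat.tocsr(), resolution_kb, weights=weights,
                      state="raw" if weights is None else "balanced")


def dense_tsv(cmap: ContactMap, path) -> None:
    """Plain dense TSV for small maps (commented header with bin labels)."""
    labels = [f"{c}:{s}" for c, s in zip(cmap.bins["chrom"],
                                         cmap.bins["start"])]
    with open(path, "w") as fh:
        fh.write("# symmetric contact matrix; bins: " + ",".join(labels) + "\n")
        np.savetxt(fh, cmap.dense(), fmt="%g", delimiter="\t")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def config_hash(meta: dict) -> str:
    return hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()).hexdigest()[:16]


def save_trajectory(traj: Trajectory, path, rep_time=None, events=None,
                    meta: dict | None = None) -> None:
    """Self-describing archive: frame times/positions/fork ids, per-monomer
    bin and sister-chromatid labels, replication times, metadata block."""
    meta = dict(meta or {})
    meta.setdefault("step_nm", traj.step_nm)
    meta.setdefault("time_per_mcs_ms", traj.time_per_mcs_ms)
    meta["config_hash"] = meta.get("config_hash") or config_hash(meta)
    n_mon = np.array([len(p) for p in traj.positions], dtype=np.int64)
    pos = (np.concatenate(traj.positions, axis=0) if len(traj)
           else np.zeros((0, 3), np.int16))
    nf = np.array([len(f) for f in traj.fork_monomers], dtype=np.int64)
    forks = (np.concatenate(traj.fork_monomers) if len(traj)
             else np.zeros(0, np.int64))
    nmax = int(n_mon.max()) if len(n_mon) else 0
    np.savez_compressed(
        path,
        times=np.asarray(traj.times),
        n_mon=n_mon, pos=pos, n_forks=nf, forks=forks,
        gbin=(traj.gbin[:nmax] if traj.gbin is not None else np.zeros(0)),
        sc=(traj.sc[:nmax] if traj.sc is not None else np.zeros(0)),
        n_bins=np.int64(traj.n_bins),
        rep_time=(rep_time if rep_time is not None else np.zeros(0)),
        events=(events if events is not None else np.zeros((0, 3))),
        meta=json.dumps(meta))


def load_trajectory(path):
    """Returns (Trajectory, rep_time, events, meta)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        traj = Trajectory(step_nm=meta["step_nm"],
                          time_per_mcs_ms=meta["time_per_mcs_ms"])
        off = 0
        foff = 0
        for t, nm, nf in zip(z["times"], z["n_mon"], z["n_forks"]):
            traj.add(t, z["pos"][off:off + nm], z["forks"][foff:foff + nf])
            off += nm
            foff += nf
        traj.gbin = z["gbin"] if len(z["gbin"]) else None
        traj.sc = z["sc"] if len(z["sc"]) else None
        traj.n_bins = int(z["n_bins"])
        rep_time = z["rep_time"] if len(z["rep_time"]) else None
        events = z["events"]
    return traj, rep_time, events, meta


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def table_tsv(df: pd.DataFrame, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)
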