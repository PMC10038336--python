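"""File formats shared by the pipeline stages.

All tabular artifacts are plain CSV; the chromophore lattice can also be
exported as a pseudo-atom PDB file (one HETATM per PCB site, occupancy
1.00 for α, 0.50 for β) with a JSON sidecar carrying the dipoles and
helix metadata, so the geometry can be inspected in any structure viewer.
Writes are atomic (temp file + rename); readers validate grids and raise
``FrlapParseError`` with a line number on malformed input.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .globalfit import TADataset
from .helix import (ChromophoreLattice, ChromophoreSite, HelicalParams,
                    PlacementParams)
from .photophysics import RateMatrix, SpectralModel

__all__ = [
    "FrlapParseError",
    "write_spectrum_csv", "read_spectrum_csv",
    "write_lattice_csv", "read_lattice_csv",
    "write_lattice_pdb", "read_lattice_pdb",
    "write_rate_matrix", "read_rate_matrix",
    "write_ta_csv", "read_ta_csv",
    "write_tcspc_csv", "read_tcspc_csv",
    "write_json", "read_json",
]


class FrlapParseError(ValueError):
    pass


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(path: str | Path, payload: dict) -> None:
    _atomic_write(path, json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# --- spectra ---------------------------------------------------------------

def write_spectrum_csv(path: str | Path, spectrum: SpectralModel) -> None:
    lines = [f"# site_class={spectrum.site_class}",
             "wavelength_nm,absorption_M-1cm-1,emission_norm"]
    for lam, a, e in zip(spectrum.grid, spectrum.absorption,
                         spectrum.emission):
        lines.append(f"{lam:.6g},{a:.8g},{e:.8g}")
    _atomic_write(path, "\n".join(lines) + "\n")


def read_spectrum_csv(path: str | Path) -> SpectralModel:
    site_class = "unknown"
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        if "site_class=" in first:
            site_class = first.split("site_class=")[1].strip()
    df = pd.read_csv(path, skiprows=skip)
    grid = df.iloc[:, 0].to_numpy(float)
    if np.any(~np.isfinite(df.to_numpy(float))):
        raise FrlapParseError(f"{path}: non-finite values")
    if np.any(np.diff(grid) <= 0):
        raise FrlapParseError(f"{path}: wavelength grid not increasing")
    absorption = df.iloc[:, 1].to_numpy(float)
    emission = df.iloc[:, 2].to_numpy(float)
    return SpectralModel(site_class=site_class, grid=grid,
                         absorption=absorption, emission=emission,
                         peak_abs=float(grid[np.argmax(absorption)]),
                         peak_em=float(grid[np.argmax(emission)]))


# --- lattice ---------------------------------------------------------------

def write_lattice_csv(path: str | Path, lattice: ChromophoreLattice) -> None:
    rows = ["site_id,protomer,class,x,y,z,dx,dy,dz"]
    for s in lattice.sites:
        x, y, z = s.position
        dx, dy, dz = s.dipole
        rows.append(f"{s.site_id},{s.protomer_index},{s.subunit_class},"
                    f"{x:.9f},{y:.9f},{z:.9f},{dx:.9f},{dy:.9f},{dz:.9f}")
    _atomic_write(path, "\n".join(rows) + "\n")


def _lattice_from_table(df: pd.DataFrame, helix: HelicalParams | None,
                        placement: PlacementParams | None
                        ) -> ChromophoreLattice:
    sites = [
        ChromophoreSite(site_id=int(r["site_id"]),
                        protomer_index=int(r["protomer"]),
                        subunit_class=str(r["class"]),
                        position=np.array([r["x"], r["y"], r["z"]], float),
                        dipole=np.array([r["dx"], r["dy"], r["dz"]], float),
                        site_energy_label=str(r["class"]))
        for _, r in df.iterrows()
    ]
    return ChromophoreLattice(sites=sites,
                              helix=helix or HelicalParams(),
                              placement=placement or PlacementParams())


def read_lattice_csv(path: str | Path,
                     helix: HelicalParams | None = None,
                     placement: PlacementParams | None = None
                     ) -> ChromophoreLattice:
    df = pd.read_csv(path)
    required = {"site_id", "protomer", "class", "x", "y", "z",
                "dx", "dy", "dz"}
    if not required <= set(df.columns):
        raise FrlapParseError(f"{path}: missing columns "
                              f"{sorted(required - set(df.columns))}")
    df = df.rename(columns={"class": "class"})
    return _lattice_from_table(df, helix, placement)


def write_lattice_pdb(path: str | Path,
                      lattice: ChromophoreLattice) -> None:
    """Pseudo-atom PDB (one HETATM per site) plus a JSON dipole sidecar."""
    st = gemmi.Structure()
    st.name = "FRLAP chromophore lattice"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for s in lattice.sites:
        res = gemmi.Residue()
        res.name = "PCB"
        res.seqid = gemmi.SeqId(s.protomer_index + 1, " ")
        res.het_flag = "H"
        atom = gemmi.Atom()
        atom.name = "CA" if s.subunit_class == "alpha" else "CB"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*s.position)
        atom.occ = 1.0 if s.subunit_class == "alpha" else 0.5
        atom.b_iso = float(s.site_id)
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    sidecar = {
        "helix": {"protomers_per_repeat": lattice.helix.protomers_per_repeat,
                  "degrees_per_repeat": lattice.helix.degrees_per_repeat,
                  "rise_per_repeat": lattice.helix.rise_per_repeat,
                  "handedness": lattice.helix.handedness},
        "dipoles": {str(s.site_id): [float(v) for v in s.dipole]
                    for s in lattice.sites},
        "classes": {str(s.site_id): s.subunit_class
                    for s in lattice.sites},
    }
    write_json(str(path) + ".json", sidecar)


def read_lattice_pdb(path: str | Path,
                     helix: HelicalParams | None = None,
                     placement: PlacementParams | None = None
                     ) -> ChromophoreLattice:
    st = gemmi.read_structure(str(path))
    sidecar = read_json(str(path) + ".json")
    rows = []
    sid = 0
    for chain in st[0]:
        for res in chain:
            for atom in res:
                cls = sidecar["classes"][str(sid)]
                dip = sidecar["dipoles"][str(sid)]
                rows.append(dict(site_id=sid, protomer=res.seqid.num - 1,
                                 **{"class": cls},
                                 x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                                 dx=dip[0], dy=dip[1], dz=dip[2]))
                sid += 1
    if helix is None and "helix" in sidecar:
        helix = HelicalParams(**sidecar["helix"])
    return _lattice_from_table(pd.DataFrame(rows), helix, placement)


# --- rate matrix -----------------------------------------------------------

def write_rate_matrix(path: str | Path, rm: RateMatrix) -> None:
    df = pd.DataFrame(rm.K, index=rm.site_ids, columns=rm.site_ids)
    _atomic_write(path, df.to_csv(index_label="site_id"))
    write_json(str(path) + ".json",
               {"decay_per_site": rm.decay.tolist(),
                "trap_per_site": rm.trap.tolist(),
                "meta": rm.meta})


def read_rate_matrix(path: str | Path) -> RateMatrix:
    df = pd.read_csv(path, index_col=0)
    K = df.to_numpy(float)
    if K.shape[0] != K.shape[1]:
        raise FrlapParseError(f"{path}: rate matrix not square")
    if np.any(~np.isfinite(K)):
        raise FrlapParseError(f"{path}: non-finite rates")
    side = read_json(str(path) + ".json")
    return RateMatrix(K=K, site_ids=df.index.to_numpy(int),
                      decay=np.array(side["decay_per_site"], float),
                      trap=np.array(side["trap_per_site"], float),
                      meta=side.get("meta", {}))


# --- TA matrix -------------------------------------------------------------

def write_ta_csv(path: str | Path, ta: TADataset) -> None:
    """Plain-matrix dialect: first row wavelengths (nm), first column
    delays (ps), cells ΔOD (mOD)."""
    df = pd.DataFrame(ta.delta_od, index=ta.time_ps,
                      columns=ta.wavelength_nm)
    _atomic_write(path, df.to_csv(index_label="delay_ps"))
    write_json(str(path) + ".json",
               {"excitation_nm": ta.excitation_nm, "meta": ta.meta})


def read_ta_csv(path: str | Path) -> TADataset:
    df = pd.read_csv(path, index_col=0)
    try:
        wavelengths = df.columns.to_numpy(float)
    except ValueError as exc:
        raise FrlapParseError(f"{path}: header row is not numeric "
                              f"wavelengths ({exc})") from exc
    delays = df.index.to_numpy(float)
    data = df.to_numpy(float)
    if np.any(~np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))[0]
        raise FrlapParseError(f"{path}: non-finite ΔOD at data row "
                              f"{bad[0] + 2}")
    meta: dict = {}
    excitation = 580.0
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        side = read_json(sidecar)
        meta = side.get("meta", {})
        excitation = side.get("excitation_nm", excitation)
    try:
        return TADataset(time_ps=delays, wavelength_nm=wavelengths,
                         delta_od=data, excitation_nm=excitation, meta=meta)
    except ValueError as exc:
        raise FrlapParseError(f"{path}: {exc}") from exc


# --- TCSPC -----------------------------------------------------------------

def write_tcspc_csv(path: str | Path, time_ps: np.ndarray,
                    counts: np.ndarray) -> None:
    lines = ["time_ps,counts"]
    lines += [f"{t:.6g},{c:.10g}" for t, c in zip(time_ps, counts)]
    _atomic_write(path, "\n".join(lines) + "\n")


def read_tcspc_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(float)
    c = df.iloc[:, 1].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise FrlapParseError(f"{path}: time axis not increasing")
    if np.any(c < 0):
        raise FrlapParseError(f"{path}: negative counts")
    return t, c
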