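"""Reading and writing LC-MS runs and gridded tensors.

mzXML parsing is delegated to pyteomics; mzML spectra are read by a compact
namespace-agnostic parser covering the spectrum subset the pipeline needs
(centroid MS1 peak lists, 32/64-bit float arrays, zlib or no compression).
Only MS1 scans are kept — the fingerprint method works on TIC-mode MS1 data.
Gridded tensors are stored as one ``.npy`` matrix per sample plus a JSON
sidecar holding the grids and sample metadata.  A matching mzML serializer is
provided so synthetic runs round-trip through the same reader as real data.
"""

from __future__ import annotations

import base64
import json
import struct
import xml.etree.ElementTree as ET
import zlib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pyteomics import mzxml as _mzxml

from .core import (
    DatasetTensor,
    EmptyRunError,
    GriddedSample,
    MassGrid,
    RawRun,
    ScanRecord,
    TimeGrid,
)

MANIFEST_COLUMNS = ("sample_id", "specimen_id", "replicate", "label", "path")


def _rt_minutes(value) -> float:
    """Convert a pyteomics retention-time value to minutes."""
    unit = getattr(value, "unit_info", None)
    v = float(value)
    if unit and "second" in str(unit):
        return v / 60.0
    return v


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: (array name, values)."""
    dtype = "<f8"
    compressed = False
    name = None
    payload = ""
    for el in bda.iter():
        t = _local(el.tag)
        if t == "cvParam":
            acc = el.get("accession")
            if acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                name = "mz"
            elif acc == "MS:1000515":
                name = "intensity"
        elif t == "binary":
            payload = el.text or ""
    data = base64.b64decode(payload)
    if compressed:
        data = zlib.decompress(data)
    return name, np.frombuffer(data, dtype=dtype).astype(np.float64)


def _scans_from_mzml(path: Path) -> list[ScanRecord]:
    """Minimal mzML spectrum reader (centroid MS1; 32/64-bit, zlib or raw).

    Namespace-agnostic so plain and indexed mzML both parse.
    """
    scans = []
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        ms_level = 1
        rt = None
        arrays: dict[str, np.ndarray] = {}
        for el in elem.iter():
            if _local(el.tag) == "cvParam" and el.get("accession") == "MS:1000511":
                ms_level = int(float(el.get("value", "1")))
            elif _local(el.tag) == "cvParam" and el.get("accession") == "MS:1000016":
                rt = float(el.get("value"))
                unit = (el.get("unitName") or "").lower()
                if "second" in unit or el.get("unitAccession") == "UO:0000010":
                    rt /= 60.0
            elif _local(el.tag) == "binaryDataArray":
                name, values = _decode_binary_array(el)
                if name:
                    arrays[name] = values
        if ms_level == 1 and rt is not None:
            scans.append(
                _make_scan(rt, arrays.get("mz", []), arrays.get("intensity", []))
            )
        elem.clear()
    return scans


def _scan_from_mzxml(spectrum) -> ScanRecord | None:
    if int(spectrum.get("msLevel", 1)) != 1:
        return None
    rt = _rt_minutes(spectrum["retentionTime"])
    return _make_scan(rt, spectrum["m/z array"], spectrum["intensity array"])


def _make_scan(rt: float, mz, intensity) -> ScanRecord:
    mz = np.asarray(mz, dtype=np.float64)
    intensity = np.asarray(intensity, dtype=np.float64)
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    keep = intensity > 0  # zero-intensity points carry no signal
    return ScanRecord(rt=rt, mz=mz[keep], intensity=intensity[keep])


def read_run(path: str | Path, metadata: Mapping) -> RawRun:
    """Read one mzML/mzXML acquisition and attach sample metadata.

    Only MS1 scans are kept; scans are returned in ascending RT order.

    Parameters
    ----------
    path : path to an .mzML or .mzXML file
    metadata : mapping with keys sample_id, specimen_id, replicate, label
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such LC-MS file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix == ".mzxml":
            with _mzxml.read(str(path)) as reader:
                scans = [_scan_from_mzxml(s) for s in reader]
        else:
            scans = _scans_from_mzml(path)
    except Exception as exc:  # noqa: BLE001 - surface the offending path
        raise OSError(f"failed to parse LC-MS file {path}: {exc}") from exc
    scans = [s for s in scans if s is not None]
    if not scans:
        raise EmptyRunError(f"no MS1 scans in {path}")
    scans.sort(key=lambda s: s.rt)
    return RawRun(
        sample_id=str(metadata["sample_id"]),
        specimen_id=str(metadata["specimen_id"]),
        replicate=int(metadata["replicate"]),
        label=str(metadata["label"]),
        scans=scans,
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV sample manifest (sample_id, specimen_id, replicate, label, path)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "specimen_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def read_runs(manifest: pd.DataFrame, base_dir: str | Path | None = None) -> list[RawRun]:
    base = Path(base_dir) if base_dir is not None else None
    runs = []
    for row in manifest.to_dict("records"):
        p = Path(row["path"])
        if base is not None and not p.is_absolute():
            p = base / p
        runs.append(read_run(p, row))
    return runs


# ---------------------------------------------------------------------------
# minimal mzML writer


def _b64(values: np.ndarray) -> str:
    data = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=np.float64))
    return base64.b64encode(data).decode("ascii")


def _cv(parent, accession, name, value="", unit=None):
    attrib = {"cvRef": "MS", "accession": accession, "name": name, "value": str(value)}
    if unit is not None:
        attrib.update(
            unitCvRef="UO", unitAccession=unit[0], unitName=unit[1]
        )
    ET.SubElement(parent, "cvParam", attrib)


def write_mzml(run: RawRun, path: str | Path) -> Path:
    """Serialize a run as centroided MS1 mzML (64-bit floats, no compression)."""
    path = Path(path)
    root = ET.Element(
        "mzML",
        {
            "xmlns": "http://psi.hupo.org/ms/mzml",
            "version": "1.1.0",
            "id": run.sample_id,
        },
    )
    cv_list = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(
        cv_list,
        "cv",
        {
            "id": "MS",
            "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
            "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
        },
    )
    ET.SubElement(
        cv_list,
        "cv",
        {
            "id": "UO",
            "fullName": "Unit Ontology",
            "URI": "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
        },
    )
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")
    soft_list = ET.SubElement(root, "softwareList", {"count": "1"})
    ET.SubElement(soft_list, "software", {"id": "msfingerprint", "version": "0.1.0"})
    icl = ET.SubElement(root, "instrumentConfigurationList", {"count": "1"})
    ET.SubElement(icl, "instrumentConfiguration", {"id": "IC1"})
    dpl = ET.SubElement(root, "dataProcessingList", {"count": "1"})
    dp = ET.SubElement(dpl, "dataProcessing", {"id": "dp1"})
    pm = ET.SubElement(dp, "processingMethod", {"order": "0", "softwareRef": "msfingerprint"})
    _cv(pm, "MS:1000544", "Conversion to mzML")

    mz_run = ET.SubElement(
        root, "run", {"id": run.sample_id, "defaultInstrumentConfigurationRef": "IC1"}
    )
    spec_list = ET.SubElement(
        mz_run,
        "spectrumList",
        {"count": str(len(run.scans)), "defaultDataProcessingRef": "dp1"},
    )
    for i, scan in enumerate(run.scans):
        spec = ET.SubElement(
            spec_list,
            "spectrum",
            {
                "index": str(i),
                "id": f"scan={i + 1}",
                "defaultArrayLength": str(len(scan.mz)),
            },
        )
        _cv(spec, "MS:1000579", "MS1 spectrum")
        _cv(spec, "MS:1000511", "ms level", 1)
        _cv(spec, "MS:1000127", "centroid spectrum")
        scans_el = ET.SubElement(spec, "scanList", {"count": "1"})
        _cv(scans_el, "MS:1000795", "no combination")
        scan_el = ET.SubElement(scans_el, "scan")
        _cv(
            scan_el,
            "MS:1000016",
            "scan start time",
            scan.rt,
            unit=("UO:0000031", "minute"),
        )
        bdal = ET.SubElement(spec, "binaryDataArrayList", {"count": "2"})
        for accession, name, values in (
            ("MS:1000514", "m/z array", scan.mz),
            ("MS:1000515", "intensity array", scan.intensity),
        ):
            payload = _b64(values)
            bda = ET.SubElement(
                bdal, "binaryDataArray", {"encodedLength": str(len(payload))}
            )
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            if accession == "MS:1000514":
                _cv(bda, accession, name, unit=("MS:1000040", "m/z"))
            else:
                _cv(
                    bda,
                    accession,
                    name,
                    unit=("MS:1000131", "number of detector counts"),
                )
            ET.SubElement(bda, "binary").text = payload
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# gridded tensor container

_SIDECAR = "tensor.json"


def save_tensor(tensor: DatasetTensor, out_dir: str | Path) -> Path:
    """Write one .npy per sample plus a JSON sidecar with grids and metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, s in enumerate(tensor):
        fname = f"sample_{i:05d}.npy"
        np.save(out_dir / fname, s.matrix)
        records.append(
            {
                "sample_id": s.sample_id,
                "specimen_id": s.specimen_id,
                "replicate": s.replicate,
                "label": s.label,
                "parent_id": s.parent_id,
                "provenance": s.provenance,
                "file": fname,
            }
        )
    tg, mg = tensor.time_grid, tensor.mass_grid
    sidecar = {
        "time_grid": {"t_start": tg.t_start, "t_step": tg.t_step, "n_points": tg.n_points},
        "mass_grid": {
            "mz_first": mg.mz_first,
            "n_bins": mg.n_bins,
            "residual_low": mg.residual_low,
            "residual_high": mg.residual_high,
        },
        "samples": records,
    }
    (out_dir / _SIDECAR).write_text(json.dumps(sidecar, indent=1))
    return out_dir


def load_tensor(in_dir: str | Path) -> DatasetTensor:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / _SIDECAR).read_text())
    tg = TimeGrid(**sidecar["time_grid"])
    mg = MassGrid(**sidecar["mass_grid"])
    samples = []
    for rec in sidecar["samples"]:
        matrix = np.load(in_dir / rec["file"])
        samples.append(
            GriddedSample(
                sample_id=rec["sample_id"],
                specimen_id=rec["specimen_id"],
                replicate=rec["replicate"],
                label=rec["label"],
                matrix=matrix,
                time_grid=tg,
                mass_grid=mg,
                parent_id=rec.get("parent_id"),
                provenance=rec.get("provenance"),
            )
        )
    return DatasetTensor(samples)
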