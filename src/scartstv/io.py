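"""Structure-set readers and writers.

Two on-disk formats are supported:

* a JSON contour dialect —
  ``{"format_version": "1.0", "units": "mm", "structures": [{"name":
  str, "slices": [{"z": float, "vertices": [[x, y], ...]}]}]}`` —
  serialized with sorted keys and all coordinates printed with a fixed
  ``%.3f`` format (1 um), so the same document always produces identical
  bytes;
* DICOM RT Structure Set (CLOSED_PLANAR contours only), read and written
  with pydicom.  Written files are standalone by default: they carry a
  generated frame-of-reference UID and reference no image series, which
  suits synthetic phantom data; importing into a clinical TPS may
  require the referenced CT series.

The pipeline operates exclusively on contour structures: no CT image or
intensity information is read or needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .contour import COPLANARITY_TOL, ContourSlice, Structure
from .errors import ScartError, UnsupportedGeometryError

__all__ = ["ContourDocument", "read_structures", "write_structures"]

FORMAT_VERSION = "1.0"
RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"


@dataclass
class ContourDocument:
    """A set of named structures plus document-level metadata."""

    structures: list[Structure]
    patient_id: str | None = None
    frame_of_reference: str | None = None
    format_version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        names = [s.name for s in self.structures]
        if len(names) != len(set(names)):
            raise ScartError(f"structure names must be unique within a document: {names}")

    def __getitem__(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(f"no structure named {name!r}; have {[s.name for s in self.structures]}")


class ParseError(ScartError):
    """Malformed structure-set file."""


# ---------------------------------------------------------------- JSON

def _f3(x: float) -> str:
    return f"{x:.3f}"


def _document_to_json(doc: ContourDocument) -> str:
    """Deterministic serialization: sorted keys, fixed %.3f floats."""
    parts = ['{"format_version": "%s"' % doc.format_version]
    if doc.patient_id is not None:
        parts.append(', "patient_id": %s' % json.dumps(doc.patient_id))
    parts.append(', "structures": [')
    s_parts = []
    for s in doc.structures:
        sl_parts = []
        for sl in s.slices:
            verts = ", ".join(f"[{_f3(x)}, {_f3(y)}]" for x, y in sl.vertices)
            sl_parts.append('{"vertices": [%s], "z": %s}' % (verts, _f3(sl.z)))
        s_parts.append(
            '{"name": %s, "slices": [%s]}' % (json.dumps(s.name), ", ".join(sl_parts))
        )
    parts.append(", ".join(s_parts))
    parts.append('], "units": "mm"}')
    return "".join(parts)


def _document_from_json(path: Path) -> ContourDocument:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from None
    if not isinstance(payload, dict) or "structures" not in payload:
        raise ParseError(f"{path}: missing top-level 'structures' array")
    if payload.get("units", "mm") != "mm":
        raise ParseError(f"{path}: units must be mm, got {payload.get('units')!r}")
    structures = []
    for i, s in enumerate(payload["structures"]):
        try:
            slices = [ContourSlice(sl["z"], np.asarray(sl["vertices"], dtype=float))
                      for sl in s["slices"]]
            structures.append(Structure(s["name"], slices))
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: structure item {i} malformed ({exc})") from None
    return ContourDocument(structures, patient_id=payload.get("patient_id"))


# ------------------------------------------------------------ RT-STRUCT

def _document_to_rtstruct(doc: ContourDocument) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTSTRUCT_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.PatientID = doc.patient_id or "ANON"
    ds.PatientName = doc.patient_id or "ANON"
    ds.StructureSetLabel = "scartstv"
    for_uid = doc.frame_of_reference or generate_uid()

    ref_for = Dataset()
    ref_for.FrameOfReferenceUID = for_uid
    ds.ReferencedFrameOfReferenceSequence = [ref_for]

    roi_seq, contour_seq, obs_seq = [], [], []
    for number, s in enumerate(doc.structures, start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = s.name
        roi.ReferencedFrameOfReferenceUID = for_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        items = []
        for sl in s.slices:
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            item.NumberOfContourPoints = sl.n_vertices
            data = []
            for x, y in sl.vertices:
                data.extend([f"{x:.3f}", f"{y:.3f}", f"{sl.z:.3f}"])
            item.ContourData = data
            items.append(item)
        rc.ContourSequence = items
        contour_seq.append(rc)

        obs = Dataset()
        obs.ObservationNumber = number
        obs.ReferencedROINumber = number
        obs.RTROIInterpretedType = ""
        obs.ROIInterpreter = ""
        obs_seq.append(obs)

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.RTROIObservationsSequence = obs_seq
    return ds


def _document_from_rtstruct(path: Path) -> ContourDocument:
    try:
        ds = pydicom.dcmread(str(path), force=True)
    except Exception as exc:  # pydicom raises a mix of error types
        raise ParseError(f"{path}: cannot read DICOM ({exc})") from None
    if "ROIContourSequence" not in ds or "StructureSetROISequence" not in ds:
        raise ParseError(f"{path}: not an RT Structure Set (missing ROI sequences)")
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    structures = []
    for rc in ds.ROIContourSequence:
        name = names.get(int(rc.ReferencedROINumber), f"ROI_{rc.ReferencedROINumber}")
        slices = []
        for j, item in enumerate(getattr(rc, "ContourSequence", [])):
            gtype = str(item.ContourGeometricType)
            if gtype != "CLOSED_PLANAR":
                raise UnsupportedGeometryError(
                    f"{path}: ROI {name!r} contour item {j} has geometric type "
                    f"{gtype}; only CLOSED_PLANAR is supported"
                )
            coords = np.asarray([float(v) for v in item.ContourData]).reshape(-1, 3)
            z_vals = coords[:, 2]
            if np.ptp(z_vals) > COPLANARITY_TOL:
                raise ParseError(
                    f"{path}: ROI {name!r} contour item {j} is not coplanar "
                    f"(z spread {np.ptp(z_vals):.4f} mm)"
                )
            slices.append(ContourSlice(float(z_vals[0]), coords[:, :2]))
        structures.append(Structure(name, slices))
    pid = str(getattr(ds, "PatientID", "")) or None
    for_uid = None
    seq = getattr(ds, "ReferencedFrameOfReferenceSequence", None)
    if seq:
        for_uid = str(seq[0].FrameOfReferenceUID)
    return ContourDocument(structures, patient_id=pid, frame_of_reference=for_uid)


# ------------------------------------------------------------- facade

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".dcm", ".dicom"):
        return "rtstruct"
    try:
        with open(path, "rb") as fh:
            head = fh.read(132)
    except OSError as exc:
        raise ParseError(f"{path}: {exc}") from None
    if head[128:132] == b"DICM":
        return "rtstruct"
    if head.lstrip()[:1] == b"{":
        return "json"
    raise ParseError(f"{path}: cannot auto-detect format (not JSON or DICOM)")


def read_structures(path, format: str = "auto") -> ContourDocument:
    """Read a structure set from JSON or DICOM RT-STRUCT.

    ``format`` may be ``auto`` (detected from extension or magic bytes),
    ``json`` or ``rtstruct``.
    """
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    if format == "json":
        return _document_from_json(path)
    if format == "rtstruct":
        return _document_from_rtstruct(path)
    raise ValueError(f"unknown format {format!r}")


def write_structures(doc: ContourDocument, path, format: str = "auto") -> None:
    """Write a structure set to JSON or DICOM RT-STRUCT.

    JSON output is byte-stable (sorted keys, fixed %.3f floats).
    RT-STRUCT output is standalone: generated frame-of-reference UID,
    no referenced image series.
    """
    path = Path(path)
    if format == "auto":
        format = "rtstruct" if path.suffix.lower() in (".dcm", ".dicom") else "json"
    if format == "json":
        path.write_text(_document_to_json(doc))
    elif format == "rtstruct":
        _document_to_rtstruct(doc).save_as(str(path), enforce_file_format=True)
    else:
        raise ValueError(f"unknown format {format!r}")
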