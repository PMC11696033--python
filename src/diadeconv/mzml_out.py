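"""Serialization of pseudo-MS/MS spectra as a DDA-like, centroided mzML file.

The writer emits an indexed mzML 1.1 document with MS-level-2 spectra:
64-bit m/z arrays, 32-bit intensity arrays, no compression by default (so
byte output is deterministic for a fixed input and tool-version string),
selected-ion m/z and charge, scan start time in seconds, and the inverse
reduced ion mobility as a scan attribute (MS:1002815).  A spectrum index and
SHA-1 file checksum are appended per the indexed-mzML convention.

An MGF export with the same records is provided for engines that prefer it,
and :func:`read_mzml` parses the subset this module writes (round-trip
convenience; the test suite keeps its own independent parser).
"""

from __future__ import annotations

import base64
import hashlib
import struct
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence
from xml.sax.saxutils import escape, quoteattr

import numpy as np

from .pseudo_msms import PseudoSpectrum

__all__ = ["SpectrumRecord", "write_mzml", "write_mgf", "read_mzml", "MzmlWriteError"]

TOOL_NAME = "diadeconv"
TOOL_VERSION = "0.1.0"


class MzmlWriteError(ValueError):
    """Input cannot be serialized as a valid spectrum list."""


@dataclass
class SpectrumRecord:
    """One normalized, centroided MS2 record ready for serialization."""

    index: int
    title: str
    precursor_mz: float
    charge: int
    rt_seconds: float
    inv_k0: float
    mz_array: np.ndarray
    intensity_array: np.ndarray


def _normalize(spectra: Sequence[PseudoSpectrum]) -> list[SpectrumRecord]:
    ordered = sorted(spectra, key=lambda s: (s.rt, s.precursor_mz, s.charges[0]))
    records = []
    for s in ordered:
        if len(s.charges) != 1:
            raise MzmlWriteError("each PseudoSpectrum must carry exactly one charge")
        mz = np.array([f[0] for f in s.fragments], dtype=np.float64)
        inten = np.array([f[1] for f in s.fragments], dtype=np.float32)
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if np.any(inten <= 0):
            raise MzmlWriteError("spectrum intensities must be positive")
        if mz.size > 1 and np.any(np.diff(mz) <= 0):
            # merge exact duplicates is out of scope; reject non-ascending m/z
            raise MzmlWriteError("fragment m/z values must be strictly ascending")
        idx = len(records)
        title = (f"{TOOL_NAME}.p{s.precursor_id}.w{s.window_id}"
                 f".scan={idx + 1}.z={s.charges[0]}")
        records.append(
            SpectrumRecord(
                index=idx,
                title=title,
                precursor_mz=s.precursor_mz,
                charge=s.charges[0],
                rt_seconds=s.rt,
                inv_k0=s.im,
                mz_array=mz,
                intensity_array=inten,
            )
        )
    return records


def _encode(arr: np.ndarray, fmt: str, compress: bool) -> str:
    raw = struct.pack(f"<{arr.size}{fmt}", *arr.tolist())
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")


def _cv(accession: str, name: str, value: Optional[str] = None,
        unit: Optional[tuple[str, str, str]] = None) -> str:
    s = f'<cvParam cvRef="MS" accession={quoteattr(accession)} name={quoteattr(name)}'
    s += f" value={quoteattr(value if value is not None else '')}"
    if unit:
        ref, acc, uname = unit
        s += (f" unitCvRef={quoteattr(ref)} unitAccession={quoteattr(acc)}"
              f" unitName={quoteattr(uname)}")
    return s + "/>"

_U_MZ = ("MS", "MS:1000040", "m/z")
_U_SECOND = ("UO", "UO:0000010", "second")
_U_COUNTS = ("MS", "MS:1000131", "number of detector counts")
_U_VSCM2 = ("MS", "MS:1002814", "volt-second per square centimeter")


def _spectrum_xml(rec: SpectrumRecord, compress: bool) -> str:
    mz_b64 = _encode(rec.mz_array, "d", compress)
    in_b64 = _encode(rec.intensity_array, "f", compress)
    comp_cv = (_cv("MS:1000574", "zlib compression") if compress
               else _cv("MS:1000576", "no compression"))
    lines = [
        f'<spectrum index="{rec.index}" id="scan={rec.index + 1}" '
        f'defaultArrayLength="{rec.mz_array.size}">',
        _cv("MS:1000511", "ms level", "2"),
        _cv("MS:1000580", "MSn spectrum"),
        _cv("MS:1000127", "centroid spectrum"),
        _cv("MS:1000796", "spectrum title", rec.title),
        '<scanList count="1">',
        _cv("MS:1000795", "no combination"),
        "<scan>",
        _cv("MS:1000016", "scan start time", repr(rec.rt_seconds), _U_SECOND),
        _cv("MS:1002815", "inverse reduced ion mobility", repr(rec.inv_k0), _U_VSCM2),
        "</scan>",
        "</scanList>",
        '<precursorList count="1">',
        "<precursor>",
        '<selectedIonList count="1">',
        "<selectedIon>",
        _cv("MS:1000744", "selected ion m/z", repr(rec.precursor_mz), _U_MZ),
        _cv("MS:1000041", "charge state", str(rec.charge)),
        "</selectedIon>",
        "</selectedIonList>",
        "<activation>",
        _cv("MS:1000044", "dissociation method"),
        "</activation>",
        "</precursor>",
        "</precursorList>",
        '<binaryDataArrayList count="2">',
        f'<binaryDataArray encodedLength="{len(mz_b64)}">',
        _cv("MS:1000523", "64-bit float"),
        comp_cv,
        _cv("MS:1000514", "m/z array", unit=_U_MZ),
        f"<binary>{mz_b64}</binary>",
        "</binaryDataArray>",
        f'<binaryDataArray encodedLength="{len(in_b64)}">',
        _cv("MS:1000521", "32-bit float"),
        comp_cv,
        _cv("MS:1000515", "intensity array", unit=_U_COUNTS),
        f"<binary>{in_b64}</binary>",
        "</binaryDataArray>",
        "</binaryDataArrayList>",
        "</spectrum>",
    ]
    return "".join(lines)


def write_mzml(spectra: Sequence[PseudoSpectrum], path, *,
               compress: bool = False, allow_empty: bool = False,
               run_id: str = "run1",
               tool_version: str = TOOL_VERSION) -> None:
    """Write an indexed mzML file; byte-deterministic for fixed inputs."""
    records = _normalize(spectra)
    if not records and not allow_empty:
        raise MzmlWriteError("refusing to write an empty mzML (set allow_empty)")

    head_parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<indexedmzML xmlns="http://psi.hupo.org/ms/mzml" '
        'xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance" '
        'xsi:schemaLocation="http://psi.hupo.org/ms/mzml '
        'http://psidev.info/files/ms/mzML/xsd/mzML1.1.2_idx.xsd">',
        f'<mzML xmlns="http://psi.hupo.org/ms/mzml" id={quoteattr(run_id)} version="1.1.0">',
        '<cvList count="2">',
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'version="4.1.0" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        '<cv id="UO" fullName="Unit Ontology" version="09:04:2014" '
        'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>',
        "</cvList>",
        "<fileDescription>",
        "<fileContent>",
        _cv("MS:1000580", "MSn spectrum"),
        _cv("MS:1000127", "centroid spectrum"),
        "</fileContent>",
        "</fileDescription>",
        '<softwareList count="1">',
        f'<software id={quoteattr(TOOL_NAME)} version={quoteattr(tool_version)}>',
        _cv("MS:1000799", "custom unreleased software tool", TOOL_NAME),
        "</software>",
        "</softwareList>",
        '<instrumentConfigurationList count="1">',
        '<instrumentConfiguration id="IC1">',
        _cv("MS:1000031", "instrument model"),
        "</instrumentConfiguration>",
        "</instrumentConfigurationList>",
        '<dataProcessingList count="1">',
        '<dataProcessing id="dp1">',
        f'<processingMethod order="0" softwareRef={quoteattr(TOOL_NAME)}>',
        _cv("MS:1000544", "Conversion to mzML"),
        "</processingMethod>",
        "</dataProcessing>",
        "</dataProcessingList>",
        f'<run id={quoteattr(run_id)} defaultInstrumentConfigurationRef="IC1">',
        f'<spectrumList count="{len(records)}" defaultDataProcessingRef="dp1">',
    ]
    head = "".join(head_parts).encode("utf-8")

    body = bytearray(head)
    offsets = []
    for rec in records:
        offsets.append((f"scan={rec.index + 1}", len(body)))
        body.extend(_spectrum_xml(rec, compress).encode("utf-8"))
    body.extend(b"</spectrumList></run></mzML>")

    index_offset = len(body)
    idx_parts = ['<indexList count="1">', '<index name="spectrum">']
    for id_ref, off in offsets:
        idx_parts.append(f'<offset idRef={quoteattr(id_ref)}>{off}</offset>')
    idx_parts.append("</index></indexList>")
    idx_parts.append(f"<indexListOffset>{index_offset}</indexListOffset>")
    body.extend("".join(idx_parts).encode("utf-8"))
    body.extend(b"<fileChecksum>")
    sha1 = hashlib.sha1(bytes(body)).hexdigest()
    body.extend(sha1.encode("ascii"))
    body.extend(b"</fileChecksum></indexedmzML>\n")

    try:
        with open(path, "wb") as fh:
            fh.write(bytes(body))
    except OSError as exc:
        raise OSError(f"cannot write mzML: {exc}") from exc


def write_mgf(spectra: Sequence[PseudoSpectrum], path) -> None:
    """MGF export with the same records and ordering as the mzML output."""
    records = _normalize(spectra)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={rec.title}\n")
            fh.write(f"PEPMASS={rec.precursor_mz!r}\n")
            fh.write(f"CHARGE={rec.charge}+\n")
            fh.write(f"RTINSECONDS={rec.rt_seconds!r}\n")
            fh.write(f"ION_MOBILITY={rec.inv_k0!r}\n")
            for mz, inten in zip(rec.mz_array, rec.intensity_array):
                fh.write(f"{mz!r} {float(inten)!r}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# reading (round-trip convenience)

_NS = "{http://psi.hupo.org/ms/mzml}"


def read_mzml(path) -> list[SpectrumRecord]:
    """Parse the subset of mzML written by :func:`write_mzml`."""
    import xml.etree.ElementTree as ET

    tree = ET.parse(path)
    root = tree.getroot()
    out = []
    for spec in root.iter(f"{_NS}spectrum"):
        params = {c.get("accession"): c.get("value")
                  for c in spec.iter(f"{_NS}cvParam")}
        arrays = {}
        for bda in spec.iter(f"{_NS}binaryDataArray"):
            accs = {c.get("accession") for c in bda.iter(f"{_NS}cvParam")}
            raw = base64.b64decode(bda.find(f"{_NS}binary").text or "")
            if "MS:1000574" in accs:
                raw = zlib.decompress(raw)
            if "MS:1000523" in accs:
                vals = np.frombuffer(raw, dtype="<f8")
            else:
                vals = np.frombuffer(raw, dtype="<f4")
            if "MS:1000514" in accs:
                arrays["mz"] = vals.astype(np.float64)
            elif "MS:1000515" in accs:
                arrays["intensity"] = vals.astype(np.float32)
        out.append(
            SpectrumRecord(
                index=int(spec.get("index")),
                title=params.get("MS:1000796", ""),
                precursor_mz=float(params["MS:1000744"]),
                charge=int(params["MS:1000041"]),
                rt_seconds=float(params["MS:1000016"]),
                inv_k0=float(params["MS:1002815"]),
                mz_array=arrays.get("mz", np.empty(0)),
                intensity_array=arrays.get("intensity", np.empty(0, np.float32)),
            )
        )
    out.sort(key=lambda r: r.index)
    return out
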