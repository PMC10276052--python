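"""mzML serialization of acquisition output.

Scan streams are written as centroided mzML 1.1.  Two pieces of information
standard mzML has no slot for are carried as ``userParam`` annotations, and
this dialect is what the downstream pipeline consumes:

* ``scan_class`` (spectrum level) — MS1 / DIA / PRM_SURVEY / MSX /
  SQ_SURVEY / SQ_SENSITIVE, mirroring how vendor filter strings distinguish
  scan types;
* ``target_id`` / ``channel`` / ``fill_time_ms`` (inside each precursor's
  isolation window) — the per-precursor differential injection times of the
  multiplexed MSx scans, which the quantification step divides out.

Both directions are implemented natively: writing is a streaming text
emitter (arrays base64-encoded 64-bit floats, uncompressed) and reading is a
namespace-tolerant ``iterparse`` pass over the same elements.
"""

from __future__ import annotations

import base64
import logging
from pathlib import Path
from typing import Iterable, Sequence
from xml.etree import ElementTree as ET
from xml.sax.saxutils import quoteattr

import numpy as np
import pandas as pd

from .acquire import ScanRecord

logger = logging.getLogger(__name__)

_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://ontologies.berkeleybop.org/uo.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="hybridia" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="hybridia"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="dp1">
      <processingMethod order="1" softwareRef="hybridia">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="simulated_run" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count={count} defaultDataProcessingRef="dp1">
"""

_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, "<f8").tobytes()).decode("ascii")


def _binary_block(arr: np.ndarray, accession: str, name: str, unit: str) -> str:
    data = _b64(arr)
    return (
        f'          <binaryDataArray encodedLength="{len(data)}">\n'
        f'            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""{unit}/>\n'
        f"            <binary>{data}</binary>\n"
        f"          </binaryDataArray>\n"
    )


def _spectrum_xml(scan: ScanRecord, index: int) -> str:
    ms_level = 1 if scan.scan_class == "MS1" else 2
    n = int(scan.mz.size)
    out = [
        f'      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{n}">\n'
        f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>\n'
        f'        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
        f'        <userParam name="scan_class" value={quoteattr(scan.scan_class)} type="xsd:string"/>\n'
        f'        <userParam name="cycle_index" value="{scan.cycle_index}" type="xsd:integer"/>\n'
        f'        <userParam name="duration_s" value="{scan.duration:.9g}" type="xsd:double"/>\n'
        f'        <userParam name="scan_fill_ms" value="{scan.fill_ms:.9g}" type="xsd:double"/>\n'
        f"        <scanList count=\"1\">\n"
        f'          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>\n'
        f"          <scan>\n"
        f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
        f'value="{scan.start / 60.0:.10g}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>\n'
        f"          </scan>\n"
        f"        </scanList>\n"
    ]
    if scan.isolation:
        out.append(f'        <precursorList count="{len(scan.isolation)}">\n')
        # precursors annotations align with isolation windows where present
        for k, (center, width) in enumerate(scan.isolation):
            prec = scan.precursors[k] if k < len(scan.precursors) else None
            out.append(
                "          <precursor>\n"
                "            <isolationWindow>\n"
                f'              <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{center:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
                f'              <cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{width / 2.0:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
                f'              <cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{width / 2.0:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            )
            if prec is not None:
                tid, channel, fill = prec
                out.append(
                    f"              <userParam name=\"target_id\" value={quoteattr(tid)} type=\"xsd:string\"/>\n"
                    f"              <userParam name=\"channel\" value={quoteattr(channel)} type=\"xsd:string\"/>\n"
                    f'              <userParam name="fill_time_ms" value="{fill:.9g}" type="xsd:double"/>\n'
                )
            out.append(
                "            </isolationWindow>\n"
                "            <activation>\n"
                '              <cvParam cvRef="MS" accession="MS:1000422" name="beam-type collision-induced dissociation" value=""/>\n'
                "            </activation>\n"
                "          </precursor>\n"
            )
        out.append("        </precursorList>\n")
    out.append('        <binaryDataArrayList count="2">\n')
    out.append(_binary_block(
        scan.mz, "MS:1000514", "m/z array",
        ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'))
    out.append(_binary_block(
        scan.intensity, "MS:1000515", "intensity array",
        ' unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"'))
    out.append("        </binaryDataArrayList>\n      </spectrum>\n")
    return "".join(out)


def write_mzml(scans: Sequence[ScanRecord], path) -> Path:
    """Write a scan stream as centroided mzML 1.1 (streaming)."""
    if not scans:
        raise ValueError("cannot write an empty scan list")
    starts = [s.start for s in scans]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("scan start times must be non-decreasing")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER.replace("{count}", f'"{len(scans)}"'))
        for i, scan in enumerate(scans):
            fh.write(_spectrum_xml(scan, i))
        fh.write(_FOOTER)
    return path


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _as_float(v, default=0.0) -> float:
    try:
        return float(v)
    except (TypeError, ValueError):
        return default


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _params(elem) -> dict:
    """name -> value of the direct cvParam/userParam children."""
    out = {}
    for child in elem:
        if _local(child.tag) in ("cvParam", "userParam"):
            out[child.get("name")] = child.get("value", "")
    return out


def _decode_array(bda) -> np.ndarray:
    names = _params(bda)
    text = ""
    for child in bda:
        if _local(child.tag) == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if "no compression" not in names:
        import zlib

        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in names else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float), names


def _parse_spectrum(elem, idx: int) -> ScanRecord:
    params = _params(elem)
    start_min = 0.0
    isolation: list[tuple[float, float]] = []
    precursors: list[tuple[str, str, float]] = []
    mz = np.empty(0)
    intensity = np.empty(0)
    for child in elem.iter():
        tag = _local(child.tag)
        if tag == "scan":
            start_min = _as_float(_params(child).get("scan start time"), 0.0)
        elif tag == "isolationWindow":
            p = _params(child)
            center = _as_float(p.get("isolation window target m/z"))
            width = (_as_float(p.get("isolation window lower offset"))
                     + _as_float(p.get("isolation window upper offset")))
            isolation.append((center, width))
            if "target_id" in p:
                precursors.append((str(p["target_id"]), str(p.get("channel", "")),
                                   _as_float(p.get("fill_time_ms"))))
        elif tag == "binaryDataArray":
            arr, names = _decode_array(child)
            if "m/z array" in names:
                mz = arr
            elif "intensity array" in names:
                intensity = arr
    ms_level = int(_as_float(params.get("ms level", 1)))
    return ScanRecord(
        scan_class=str(params.get("scan_class", "MS1" if ms_level == 1 else "DIA")),
        start=start_min * 60.0,
        duration=_as_float(params.get("duration_s")),
        isolation=isolation,
        precursors=precursors,
        mz=mz,
        intensity=intensity,
        cycle_index=int(_as_float(params.get("cycle_index", 0))),
        fill_ms=_as_float(params.get("scan_fill_ms")),
    )


def read_mzml(path) -> list[ScanRecord]:
    """Read a scan stream back from mzML written by :func:`write_mzml`.

    Files from other writers are accepted as long as they carry the
    ``scan_class`` and per-precursor fill-time annotations of this dialect.
    """
    scans: list[ScanRecord] = []
    idx = 0
    try:
        for event, elem in ET.iterparse(str(path), events=("end",)):
            if _local(elem.tag) == "spectrum":
                scans.append(_parse_spectrum(elem, idx))
                idx += 1
                elem.clear()
    except ET.ParseError as exc:
        raise ValueError(f"malformed mzML near spectrum index {idx}: {exc}") from None
    return scans


DIA_CLASSES = ("MS1", "DIA")
MSX_CLASSES = ("PRM_SURVEY", "MSX", "SQ_SURVEY", "SQ_SENSITIVE")


def split_hybrid(path, dia_path=None, msx_path=None):
    """Split a hybrid-DIA file into its DIA stream and its targeted MSx stream.

    Returns ``(dia_path, msx_path, fill_time_table)``: the DIA file holds
    exactly the MS1 + DIA scans, the MSx file the survey + MSx scans, and the
    table maps (scan index in the MSx file, target, channel) to the fill time
    used — the information the injection-time correction needs.  The split is
    a partition: no scan is lost or duplicated.
    """
    path = Path(path)
    dia_path = Path(dia_path) if dia_path else path.with_suffix(".dia.mzML")
    msx_path = Path(msx_path) if msx_path else path.with_suffix(".msx.mzML")
    scans = read_mzml(path)
    dia_scans = [s for s in scans if s.scan_class in DIA_CLASSES]
    msx_scans = [s for s in scans if s.scan_class in MSX_CLASSES]
    if len(dia_scans) + len(msx_scans) != len(scans):
        unknown = {s.scan_class for s in scans} - set(DIA_CLASSES) - set(MSX_CLASSES)
        raise ValueError(f"unknown scan classes in {path}: {sorted(unknown)}")
    rows = []
    for i, s in enumerate(msx_scans):
        for tid, channel, fill in s.precursors:
            rows.append({"scan_index": i, "target_id": tid,
                         "channel": channel, "fill_ms": fill})
    fill_table = pd.DataFrame(rows, columns=["scan_index", "target_id",
                                             "channel", "fill_ms"])
    for stream, out in ((dia_scans, dia_path), (msx_scans, msx_path)):
        if stream:
            write_mzml(stream, out)
        else:
            logger.warning("%s: no scans for %s; writing empty stream", path, out.name)
            with open(out, "w", encoding="utf-8") as fh:
                fh.write(_HEADER.replace("{count}", '"0"'))
                fh.write(_FOOTER)
    return dia_path, msx_path, fill_table
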