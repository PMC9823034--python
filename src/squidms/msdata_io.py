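"""mzML input/output and the in-memory run model.

Both directions are implemented directly on the mzML 1.1 schema. Reading
streams ``<spectrum>`` elements with :func:`xml.etree.ElementTree.iterparse`,
accepts only centroided MS1 scans, decodes 32/64-bit float binary arrays
(zlib-compressed or plain base64) and normalises retention times to minutes
regardless of the file's unit dialect; gzip-compressed mzML is accepted.
Writing emits a minimal, standards-conformant non-indexed document: m/z
arrays as 64-bit floats, intensity arrays as 32-bit floats, zlib-compressed,
with the CV params common readers require.
"""

from __future__ import annotations

import base64
import gzip
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape

import numpy as np

__all__ = ["Spectrum", "Run", "MzmlError", "EmptyRunError", "read_mzml", "write_mzml"]


class MzmlError(ValueError):
    """Malformed or unsupported mzML content (e.g. profile-mode spectra)."""


class EmptyRunError(MzmlError):
    """The file contains no MS1 spectra."""


@dataclass
class Spectrum:
    """One centroided MS1 scan: retention time (minutes) plus peak arrays."""

    retention_time: float
    mz_values: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.mz_values = np.asarray(self.mz_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz_values.shape != self.intensities.shape:
            raise MzmlError("mz and intensity arrays differ in length")
        if self.mz_values.size > 1 and not np.all(np.diff(self.mz_values) > 0):
            raise MzmlError("m/z values must be strictly ascending")
        if self.retention_time < 0:
            raise MzmlError("retention time must be >= 0")
        if np.any(self.intensities < 0):
            raise MzmlError("intensities must be non-negative")


@dataclass
class Run:
    """A time-ordered series of MS1 spectra with free-form acquisition metadata."""

    spectra: list[Spectrum]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [s.retention_time for s in self.spectra]
        if any(b < a for a, b in zip(times, times[1:])):
            raise MzmlError("spectra must be in non-decreasing retention-time order")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.retention_time for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)


def _local(tag: str) -> str:
    """Tag name without its XML namespace."""
    return tag.rsplit("}", 1)[-1]


_DTYPES = {"64-bit float": "<f8", "32-bit float": "<f4"}


def _decode_binary_array(element: ET.Element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, float array)."""
    dtype, compressed, kind, payload = None, False, None, ""
    for child in element.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            name = child.get("name", "")
            if name in _DTYPES:
                dtype = _DTYPES[name]
            elif name == "zlib compression":
                compressed = True
            elif name in ("m/z array", "intensity array"):
                kind = name
            elif name in ("16-bit float", "32-bit integer", "64-bit integer"):
                raise MzmlError(f"unsupported binary encoding {name!r}")
        elif tag == "binary":
            payload = child.text or ""
    if dtype is None:
        dtype = "<f8"
    raw = base64.b64decode(payload)
    if compressed and raw:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(element: ET.Element) -> Spectrum | None:
    """Build a Spectrum from one <spectrum> element; None for non-MS1 scans."""
    ms_level, rt, rt_unit, spectrum_id = 1, None, "minute", element.get("id")
    mz = inten = None
    for child in element.iter():
        if _local(child.tag) != "cvParam":
            continue
        name = child.get("name", "")
        if name == "ms level":
            ms_level = int(child.get("value", "1"))
        elif name == "profile spectrum":
            raise MzmlError(
                f"profile-mode spectrum {spectrum_id!r}; centroided MS1 data are required"
            )
        elif name == "scan start time":
            rt = float(child.get("value", "nan"))
            rt_unit = child.get("unitName", "minute")
    if ms_level != 1:
        return None
    if rt is None:
        raise MzmlError(f"spectrum {spectrum_id!r} has no scan start time")
    if rt_unit == "second":
        rt /= 60.0
    for child in element.iter():
        if _local(child.tag) == "binaryDataArray":
            kind, values = _decode_binary_array(child)
            if kind == "m/z array":
                mz = values
            elif kind == "intensity array":
                inten = values
    if mz is None or inten is None:
        raise MzmlError(f"spectrum {spectrum_id!r} lacks m/z or intensity array")
    return Spectrum(rt, mz, inten)


def read_mzml(path: str | Path) -> Run:
    """Read all MS1 spectra of a (possibly gzipped) mzML file into a :class:`Run`.

    Profile-mode spectra raise :class:`MzmlError`; a file with no MS1 spectra
    raises :class:`EmptyRunError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rb") as fh:
        for _, element in ET.iterparse(fh, events=("end",)):
            if _local(element.tag) == "spectrum":
                spectrum = _parse_spectrum(element)
                if spectrum is not None:
                    spectra.append(spectrum)
                element.clear()
    if not spectra:
        raise EmptyRunError(f"{path}: no MS1 spectra")
    spectra.sort(key=lambda s: s.retention_time)
    return Run(spectra=spectra, metadata={"source_path": str(path)})


def _encode_array(values: np.ndarray, dtype: str) -> str:
    packed = np.asarray(values, dtype=dtype).tobytes()
    return base64.b64encode(zlib.compress(packed)).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="squidms" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="squidms"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value="{instrument}"/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="squidms">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="DP1">
"""

_SPECTRUM_TEMPLATE = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{npeaks}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(run: Run, path: str | Path) -> Path:
    """Write a :class:`Run` to ``path`` as non-indexed mzML 1.1.

    Retention times are written in minutes; m/z as float64 and intensity as
    float32, so a read-back reproduces intensities to float32 precision.
    """
    path = Path(path)
    parts = [
        _MZML_HEADER.format(
            instrument=escape(str(run.metadata.get("source", "synthetic LC-MS run"))),
            run_id=escape(str(run.metadata.get("run_id", "run1"))),
            count=len(run.spectra),
        )
    ]
    for i, spectrum in enumerate(run.spectra):
        mz_b64 = _encode_array(spectrum.mz_values, "<f8")
        int_b64 = _encode_array(spectrum.intensities, "<f4")
        parts.append(
            _SPECTRUM_TEMPLATE.format(
                index=i,
                scan=i + 1,
                npeaks=spectrum.mz_values.size,
                rt=spectrum.retention_time,
                mz_len=len(mz_b64),
                mz_b64=mz_b64,
                int_len=len(int_b64),
                int_b64=int_b64,
            )
        )
    parts.append(_MZML_FOOTER)
    document = "".join(parts)
    ET.fromstring(document)  # well-formedness check before touching disk
    path.write_text(document)
    return path
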