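"""Shared fixtures: enrichment models, noiseless simulations, tiny mzML files."""

from __future__ import annotations

import base64
import struct
import zlib

import pytest

from iroakit.isotope_model import EnrichmentModel
from iroakit.spectra_io import CentroidSpectrum, Peak
from iroakit.synthetic_data import SimulationConfig, fixture_library


@pytest.fixture(scope="session")
def enrichment() -> EnrichmentModel:
    return EnrichmentModel()


@pytest.fixture(scope="session")
def library():
    return fixture_library()


@pytest.fixture()
def noiseless_config() -> SimulationConfig:
    """Simulation settings with every noise source disabled."""
    return SimulationConfig(
        ppm_jitter_sd=0.0, intensity_sigma=0.0, artifact_count=0, seed=0
    )


@pytest.fixture()
def fig4_spectrum() -> CentroidSpectrum:
    """Mixed-sample EI spectrum of the unknown 5-carbon metabolite.

    The two mirrored fragment pairs sit among the ubiquitous unpaired
    silylation background ions (73, 147, 103, 221).
    """
    peaks = (
        Peak(73.0468, 9.0e5),
        Peak(103.0417, 2.0e5),
        Peak(131.0883, 8.0e5),
        Peak(134.0991, 7.5e5),
        Peak(147.0654, 6.0e5),
        Peak(221.0843, 3.0e5),
        Peak(292.1345, 4.0e5),
        Peak(294.1427, 3.8e5),
    )
    return CentroidSpectrum(peaks=peaks, ionization="EI", label="yeast_unknown")


def _b64(values, fmt="d", compress=False):
    raw = struct.pack(f"<{len(values)}{fmt}", *values)
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode()


def _scan_xml(index, mz, inten, rt_min, centroid=True, compress=False):
    acc, nm = (
        ("MS:1000127", "centroid spectrum")
        if centroid
        else ("MS:1000128", "profile spectrum")
    )
    comp = (
        ("MS:1000574", "zlib compression")
        if compress
        else ("MS:1000576", "no compression")
    )
    return f"""
    <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(mz)}">
      <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
      <cvParam cvRef="MS" accession="{acc}" name="{nm}" value=""/>
      <scanList count="1">
        <scan>
          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time"
                   value="{rt_min}" unitName="minute"/>
        </scan>
      </scanList>
      <binaryDataArrayList count="2">
        <binaryDataArray>
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="{comp[0]}" name="{comp[1]}" value=""/>
          <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
          <binary>{_b64(mz, compress=compress)}</binary>
        </binaryDataArray>
        <binaryDataArray>
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="{comp[0]}" name="{comp[1]}" value=""/>
          <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
          <binary>{_b64(inten, compress=compress)}</binary>
        </binaryDataArray>
      </binaryDataArrayList>
    </spectrum>"""


@pytest.fixture()
def make_mzml(tmp_path):
    """Factory writing a minimal mzML file with the given scans.

    ``scans`` is a list of (mz_list, intensity_list, rt_minutes) triples.
    """

    def _make(scans, centroid=True, compress=False, name="test.mzml"):
        body = "".join(
            _scan_xml(i, mz, inten, rt, centroid, compress)
            for i, (mz, inten, rt) in enumerate(scans)
        )
        xml = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r1"><spectrumList count="{len(scans)}">{body}
  </spectrumList></run>
</mzML>"""
        path = tmp_path / name
        path.write_text(xml)
        return path

    return _make
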