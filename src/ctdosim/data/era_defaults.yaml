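# Era-default probability density functions for technical parameters that
# are missing from both records and protocol tables. One entry per
# (era, exam region, parameter). Later eras must not be wider than earlier
# ones for the same parameter (better documentation over time).
#
# provenance: free-text note on where the shape/width came from; these are
# editable study inputs, not measurements.
version: 1
eras:
  - name: pre_pacs
    until: "2000-01-01"
    parameters:
      kvp:
        head:    {family: discrete_joint, rows: [[120], [130], [140]], weights: [0.5, 0.2, 0.3], columns: [kvp], provenance: "era-typical head voltages"}
        chest:   {family: discrete_joint, rows: [[120], [130], [140]], weights: [0.6, 0.2, 0.2], columns: [kvp], provenance: "era-typical trunk voltages"}
        abdomen: {family: discrete_joint, rows: [[120], [130], [140]], weights: [0.6, 0.2, 0.2], columns: [kvp], provenance: "era-typical trunk voltages"}
      mas:
        head:    {family: lognormal, median: 250, gsd: 1.5, lo: 80, hi: 600, provenance: "survey-style spread for axial head protocols"}
        chest:   {family: lognormal, median: 160, gsd: 1.6, lo: 40, hi: 500, provenance: "survey-style spread"}
        abdomen: {family: lognormal, median: 200, gsd: 1.6, lo: 50, hi: 600, provenance: "survey-style spread"}
      pitch:
        head:    {family: point, value: 1.0, provenance: "contiguous axial era"}
        chest:   {family: triangular, lo: 1.0, mode: 1.0, hi: 1.5, provenance: "early helical pitch range"}
        abdomen: {family: triangular, lo: 1.0, mode: 1.0, hi: 1.5, provenance: "early helical pitch range"}
      scan_length_mm:
        head:    {family: triangular, lo: 120, mode: 150, hi: 190, provenance: "anatomical head coverage"}
        chest:   {family: triangular, lo: 150, mode: 220, hi: 320, provenance: "anatomical chest coverage"}
        abdomen: {family: triangular, lo: 150, mode: 250, hi: 400, provenance: "anatomical abdomen coverage"}
      modulation_factor:
        head:    {family: point, value: 1.0, provenance: "no current modulation pre-PACS"}
        chest:   {family: point, value: 1.0, provenance: "no current modulation pre-PACS"}
        abdomen: {family: point, value: 1.0, provenance: "no current modulation pre-PACS"}
  - name: post_pacs
    from: "2000-01-01"
    parameters:
      kvp:
        head:    {family: discrete_joint, rows: [[120], [130]], weights: [0.8, 0.2], columns: [kvp], provenance: "modern head voltages"}
        chest:   {family: discrete_joint, rows: [[100], [120]], weights: [0.4, 0.6], columns: [kvp], provenance: "modern trunk voltages"}
        abdomen: {family: discrete_joint, rows: [[100], [120]], weights: [0.3, 0.7], columns: [kvp], provenance: "modern trunk voltages"}
      mas:
        head:    {family: lognormal, median: 220, gsd: 1.3, lo: 100, hi: 450, provenance: "narrower modern spread"}
        chest:   {family: lognormal, median: 90, gsd: 1.4, lo: 30, hi: 300, provenance: "dose-reduced paediatric chest"}
        abdomen: {family: lognormal, median: 120, gsd: 1.4, lo: 40, hi: 350, provenance: "dose-reduced paediatric abdomen"}
      pitch:
        head:    {family: point, value: 1.0, provenance: "axial head convention"}
        chest:   {family: triangular, lo: 1.0, mode: 1.2, hi: 1.4, provenance: "multi-slice helical"}
        abdomen: {family: triangular, lo: 1.0, mode: 1.2, hi: 1.4, provenance: "multi-slice helical"}
      scan_length_mm:
        head:    {family: triangular, lo: 130, mode: 150, hi: 180, provenance: "anatomical head coverage"}
        chest:   {family: triangular, lo: 160, mode: 220, hi: 300, provenance: "anatomical chest coverage"}
        abdomen: {family: triangular, lo: 180, mode: 250, hi: 380, provenance: "anatomical abdomen coverage"}
      modulation_factor:
        head:    {family: point, value: 1.0, provenance: "modulation rare for head"}
        chest:   {family: triangular, lo: 0.6, mode: 0.85, hi: 1.0, provenance: "tube-current modulation dose factor"}
        abdomen: {family: triangular, lo: 0.6, mode: 0.85, hi: 1.0, provenance: "tube-current modulation dose factor"}
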