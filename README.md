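# phytomer3d

Phytomer-based 3D geometric modeling and quantitative plant-architecture
analysis for multi-tiller cereals (wheat).

A *phytomer* — internode plus leaf sheath, leaf blade and, on the top unit,
the spike — is the repeating building block of a grass shoot. This package
models each phytomer as a triple of triangle meshes, skeleton polylines and
morphological parameters, and provides:

* **digitizer I/O** (`phytomer3d.digitizer`): a documented CSV dialect for
  contact-digitizer traces (leaf surfaces as rows of left-edge/vein/right-edge
  points plus a tip — the 3n+1 convention — vein polylines, stem node and
  girth points, ear traces), leaf-surface triangulation, circumcircle stem
  diameters, and OBJ export;
* **canonical phytomer templates** (`phytomer3d.core`): naming (ranks counted
  from the top), kind classification (spike-bearing / middle / basal), and
  normalization into the template pose (internode base at the origin, axis
  vertical, leaf azimuth zero);
* **rigid-transform assembly** (`phytomer3d.assembly`): stack templates into
  tillers (per-phytomer azimuth spin + base height) and tillers into whole
  shoots (general rigid motions), with provenance labels on every component
  and similarity-based template selection;
* **multi-scale traits** (`phytomer3d.traits`): blade curvature, stem-leaf
  angle, phytomer envelope, internode lengths, stem vertical angle, plant
  height, and the convex-hull projected spike-layer area;
* **architecture quantification** (`phytomer3d.architecture`): the plant
  architecture vector PA = (C, L, PHY, S), loose / semi-compact / compact
  classification, and cultivar-panel statistics (replicate spread, Pearson
  correlations);
* **synthetic plants** (`phytomer3d.synthetic`): digitizer-format wheat
  plants with analytically known ground truth (circular-arc leaves, fanned
  leaning tillers, optional Gaussian point noise), used throughout the tests;
* **template database + CLI** (`phytomer3d.templatedb`, `phytomer3d.cli`).

Conventions: right-handed z-up coordinates, ground at z = 0, lengths in cm,
angles in degrees, azimuths CCW from +x.

## CLI

```sh
# generate a synthetic 10-cultivar panel, 3 replicates each
phytomer3d simulate --seed 0 --out plants/

# extract the trait table and classify plant architecture
phytomer3d measure plants/D1_rep1.csv plants/D2_rep1.csv --out traits.csv
phytomer3d classify --traits traits.csv --out pa.csv

# ingest a digitized plant into a template database, then assemble a shoot
phytomer3d ingest --plant plants/D1_rep1.csv --db db/ --variety D1
phytomer3d assemble --spec shoot.yaml --db db/ --out shoot.obj

# per-cultivar replicate statistics and PA correlations
phytomer3d summarize --pa pa.csv --out summary/
```

An assembly spec is YAML/JSON:

```yaml
plant: 1
tillers:
  - tiller: 1
    transform: {azimuth_deg: 0, lean_deg: 8}
    phytomers:
      - {template: 1, azimuth: 0}        # stacked base heights by default
      - {template: 2, azimuth: 180}
```

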