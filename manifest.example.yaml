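# Example pipeline manifest. Run the stages in order:
#   hextable fixtures -c manifest.example.yaml -o out/
#   hextable lattice  -c manifest.example.yaml -o out/
#   hextable ingest   -c manifest.example.yaml -o out/
#   hextable context  -c manifest.example.yaml -o out/
#   hextable query    -c manifest.example.yaml -o out/
#   hextable score    -c manifest.example.yaml -o out/

seed: 7

# study area, projected planar meters
extent: {min_x: 0, min_y: 0, max_x: 6000, max_y: 6000}

# hex sampling frame: nearest-neighbour spacing and the area threshold
# below which polygon centroids join the frame
lattice: {spacing_m: 400, area_threshold_m2: 67261}

# synthetic inputs written by the `fixtures` stage
fixtures:
  n_rows: 6            # block grid dimensions
  n_cols: 6
  cell_km: 1.0
  blocks_per_county: 4 # must be a perfect square
  n_parks: 10
  n_hospitals: 3
  rho: 0.5             # spatial autocorrelation of the county risk field

sources:
  - {source_id: census, name: toy census}

# tabular attributes, pre-registered then joined by geography key
attributes:
  - attr_id: population
    source_id: census
    native_level: county
    kind: count
    iso_category: society
    tags: [population]
    file: county_attributes.csv
    key_level: county
  - attr_id: risk_field
    source_id: census
    native_level: county
    kind: rate
    iso_category: health
    file: county_attributes.csv
    key_level: county

# count -> per-km² density columns (areas from proximal polygons)
densities:
  - {count_attr: population, level: county}

# precomputed context-measure columns
context:
  - {attr_id: dist_park, mode: distance, file: parks.geojson,
     kind: distance_m, iso_category: environment}
  - {attr_id: road_density, mode: density_grid, file: roads.geojson,
     cell_size_m: 1000, measure: line_length, kind: density,
     iso_category: transportation}
  - {attr_id: tt_hospital, mode: travel_time, facilities: hospitals.geojson,
     network: roads.geojson, kind: time_min, iso_category: health}

# boolean column-predicate query + attributes for the extract
query:
  expression: "dist_park > 400 AND road_density > 1500 AND tt_hospital <= 15"
  attrs: [population_per_km2, dist_park, road_density]

# quintile risk scoring, LISA on the composite, SKATER regions
scores:
  level: county
  k_regions: 3
  n_perm: 999
  categories:
    risk:
      - {attr: risk_field, worse_is_high: true}
    access:
      - {attr: tt_hospital, worse_is_high: true}
      - {attr: dist_park, worse_is_high: true}
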