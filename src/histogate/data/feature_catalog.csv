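name,family,units,aggregation,module
min_eccentricity_neoplastic,pleomorphism,dimensionless,min,morphometry
mean_eccentricity_neoplastic,pleomorphism,dimensionless,mean,morphometry
max_eccentricity_neoplastic,pleomorphism,dimensionless,max,morphometry
sd_eccentricity_neoplastic,pleomorphism,dimensionless,sd,morphometry
min_major_axis_length_neoplastic,pleomorphism,px,min,morphometry
mean_major_axis_length_neoplastic,pleomorphism,px,mean,morphometry
max_major_axis_length_neoplastic,pleomorphism,px,max,morphometry
sd_major_axis_length_neoplastic,pleomorphism,px,sd,morphometry
min_fractal_dimension_neoplastic,pleomorphism,dimensionless,min,morphometry
mean_fractal_dimension_neoplastic,pleomorphism,dimensionless,mean,morphometry
max_fractal_dimension_neoplastic,pleomorphism,dimensionless,max,morphometry
sd_fractal_dimension_neoplastic,pleomorphism,dimensionless,sd,morphometry
min_area_neoplastic,pleomorphism,px^2,min,morphometry
mean_area_neoplastic,pleomorphism,px^2,mean,morphometry
max_area_neoplastic,pleomorphism,px^2,max,morphometry
sd_area_neoplastic,pleomorphism,px^2,sd,morphometry
mean_eccentricity_connective,stromal_morphology,dimensionless,mean,morphometry
sd_eccentricity_connective,stromal_morphology,dimensionless,sd,morphometry
mean_major_axis_length_connective,stromal_morphology,px,mean,morphometry
sd_major_axis_length_connective,stromal_morphology,px,sd,morphometry
mean_area_connective,stromal_morphology,px^2,mean,morphometry
sd_area_connective,stromal_morphology,px^2,sd,morphometry
mean_eccentricity_inflammatory,immune_morphology,dimensionless,mean,morphometry
sd_eccentricity_inflammatory,immune_morphology,dimensionless,sd,morphometry
mean_area_inflammatory,immune_morphology,px^2,mean,morphometry
sd_area_inflammatory,immune_morphology,px^2,sd,morphometry
n_neoplastic_cells,tumor_size,cells,slide,tissue_architecture
proportion_neoplastic_cells,tumor_size,dimensionless,slide,tissue_architecture
total_tumor_area,tumor_size,px^2,slide,tissue_architecture
n_connective_cells,stroma_richness,cells,slide,tissue_architecture
proportion_connective_cells,stroma_richness,dimensionless,slide,tissue_architecture
total_stromal_area,stroma_richness,px^2,slide,tissue_architecture
tsi_stromal_area,stroma_richness,px^2,slide,tissue_architecture
distal_stromal_area,stroma_richness,px^2,slide,tissue_architecture
n_inflammatory_cells,cell_populations,cells,slide,tissue_architecture
proportion_inflammatory_cells,cell_populations,dimensionless,slide,tissue_architecture
n_macrophage_cells,cell_populations,cells,slide,tissue_architecture
proportion_macrophage_cells,cell_populations,dimensionless,slide,tissue_architecture
n_dead_cells,cell_populations,cells,slide,tissue_architecture
proportion_dead_cells,cell_populations,dimensionless,slide,tissue_architecture
n_tumor_regions,tumor_size,regions,slide,tissue_architecture
n_stroma_regions,stroma_richness,regions,slide,tissue_architecture
mean_tumor_region_area,tumor_size,px^2,mean,tissue_architecture
total_necrosis_area,tumor_size,px^2,slide,tissue_architecture
mean_count_connective_near_neoplastic,proximity,cells,mean,neighborhood
sd_count_connective_near_neoplastic,proximity,cells,sd,neighborhood
mean_fraction_connective_near_neoplastic,proximity,dimensionless,mean,neighborhood
sd_fraction_connective_near_neoplastic,proximity,dimensionless,sd,neighborhood
mean_count_inflammatory_near_neoplastic,proximity,cells,mean,neighborhood
sd_count_inflammatory_near_neoplastic,proximity,cells,sd,neighborhood
mean_fraction_inflammatory_near_neoplastic,proximity,dimensionless,mean,neighborhood
sd_fraction_inflammatory_near_neoplastic,proximity,dimensionless,sd,neighborhood
mean_count_macrophage_near_neoplastic,proximity,cells,mean,neighborhood
sd_count_macrophage_near_neoplastic,proximity,cells,sd,neighborhood
mean_fraction_macrophage_near_neoplastic,proximity,dimensionless,mean,neighborhood
sd_fraction_macrophage_near_neoplastic,proximity,dimensionless,sd,neighborhood
mean_simpson_neoplastic,proximity,dimensionless,mean,neighborhood
sd_simpson_neoplastic,proximity,dimensionless,sd,neighborhood
mean_degree_neoplastic,proximity,cells,mean,neighborhood
sd_degree_neoplastic,proximity,cells,sd,neighborhood
mean_count_inflammatory_near_inflammatory,immune_clustering,cells,mean,neighborhood
sd_count_inflammatory_near_inflammatory,immune_clustering,cells,sd,neighborhood
mean_fraction_inflammatory_near_inflammatory,immune_clustering,dimensionless,mean,neighborhood
sd_fraction_inflammatory_near_inflammatory,immune_clustering,dimensionless,sd,neighborhood
majority_inflammatory_fraction,immune_clustering,dimensionless,slide,neighborhood
mean_simpson_inflammatory,immune_clustering,dimensionless,mean,neighborhood
sd_simpson_inflammatory,immune_clustering,dimensionless,sd,neighborhood
mean_degree_inflammatory,immune_clustering,cells,mean,neighborhood
sd_degree_inflammatory,immune_clustering,cells,sd,neighborhood
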