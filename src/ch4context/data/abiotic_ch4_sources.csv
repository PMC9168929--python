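source_id,category,era,flux_min_tmol_y,flux_max_tmol_y,quality,provenance
subaerial_volcanism,magmatic,modern,,1.0e-3,ok,"Global total over ~1,500 active volcanoes each emitting <~1e-6 Tmol/y (Etiope et al. 2008; Schindler & Kasting 2000)"
submarine_volcanism,magmatic,modern,,1.0e-2,ok,"Submarine volcanism estimate (Schindler & Kasting 2000)"
midocean_ridge_serpentinization,water_rock_metamorphic,modern,,3.0e-2,ok,"Mid-ocean-ridge serpentinization; roughly three orders of magnitude below the modern biogenic flux (Keir 2010; Cannat et al. 2010)"
axial_offaxis_vents,water_rock_metamorphic,modern,1.5e-2,3.0e-2,ok,"Axial and off-axis hydrothermal vents (Catling & Kasting 2017)"
hydrothermal_modern,water_rock_metamorphic,modern,0.1,0.4,ok,"Abiotic hydrothermal systems at present (Guzman-Marmolejo et al. 2013; Kasting 2005)"
hydrothermal_hadean,water_rock_metamorphic,hadean_archean,,1.5,ok,"Hadean-maximum hydrothermal flux (Kasting 2005)"
subduction_zone_fluids,water_rock_metamorphic,modern,,1.0e-2,ok,"Subduction-zone fluids (Brovarone et al. 2020; Fiebig et al. 2019)"
continental_settings,water_rock_metamorphic,modern,,1.0e-2,ok,"Continental seeps, ophiolites, orogenic massifs and shields; several orders of magnitude below biogenic (Etiope & Sherwood Lollar 2013)"
cometary_impacts_hadean,impact,hadean_archean,,1.25,ok,"Global CH4 flux from volatile-rich cometary impactors during the Hadean (Kasting 2005; cf. 0.6 Tmol per 1-km comet, Kress & McKay 2004)"
serpentinization_catalyzed_experiments,water_rock_metamorphic,modern,,,contamination_suspect,"Catalyzed laboratory serpentinization yields; implied fluxes exceed the crustal ferrous-iron supply and organic contamination was not quantified (Oze et al. 2012; Neubeck et al. 2011; cf. McCollom 2016)"
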