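name,domain,source,applicability,value_kind
boarded_door,housing_damage,literature,parcel,binary
holes_in_walls,housing_damage,literature,parcel,binary
roof_damage,housing_damage,literature,parcel,binary
chimney_damage,housing_damage,literature,parcel,binary
foundation_damage,housing_damage,literature,parcel,binary
entry_damage,housing_damage,literature,parcel,binary
door_damage,housing_damage,literature,parcel,binary
peeling_damage,housing_damage,literature,parcel,binary
fire_damage,housing_damage,literature,parcel,binary
boarded_windows,housing_damage,literature,parcel,binary
broken_windows,housing_damage,literature,parcel,binary
condemned,housing_damage,community,parcel,binary
other_condition,housing_damage,project_leaders,parcel,text
litter,property_disorder,literature,parcel,binary
garbage,property_disorder,literature,parcel,binary
broken_glass,property_disorder,literature,parcel,binary
discarded_furniture,property_disorder,literature,parcel,binary
discarded_appliances,property_disorder,literature,parcel,binary
discarded_tires,property_disorder,literature,parcel,binary
inoperable_vehicle,property_disorder,literature,parcel,binary
high_weeds,property_disorder,literature,parcel,binary
fencing_damage,property_disorder,literature,parcel,binary
graffiti_private,property_disorder,literature,parcel,binary
cars_on_lawn,property_disorder,community,parcel,binary
no_grass,property_disorder,community,parcel,binary
standing_water,property_disorder,community,parcel,binary
other_nuisance_private,property_disorder,project_leaders,parcel,text
security_bars,territoriality,literature,parcel,binary
no_trespassing_sign,territoriality,literature,parcel,binary
security_sign,territoriality,literature,parcel,binary
fencing,territoriality,literature,parcel,binary
barbed_wire,territoriality,community,parcel,binary
beware_of_dog_sign,territoriality,community,parcel,binary
occupied,vacancy,literature,parcel,binary
unoccupied,vacancy,literature,parcel,binary
demolished,vacancy,community,parcel,binary
property_type,miscellaneous,literature,parcel,categorical
property_subtype,miscellaneous,literature,parcel,categorical
front_entry_type,miscellaneous,literature,parcel,categorical
garden,miscellaneous,literature,parcel,binary
greenery,miscellaneous,literature,parcel,binary
for_sale_sign,miscellaneous,literature,parcel,binary
for_rent_sign,miscellaneous,literature,parcel,binary
home_repair,miscellaneous,literature,parcel,binary
new_home_construction,miscellaneous,literature,parcel,binary
peeling_paint,miscellaneous,literature,parcel,binary
eviction_notice,miscellaneous,community,parcel,binary
dog,miscellaneous,community,parcel,binary
padlocked,miscellaneous,project_leaders,parcel,binary
driveway_present,miscellaneous,project_leaders,parcel,binary
fence_material,miscellaneous,project_leaders,parcel,categorical
fenced_area,miscellaneous,project_leaders,parcel,categorical
window_ac_unit,miscellaneous,project_leaders,parcel,binary
litter_public,nuisance,literature,public_space,binary
drug_paraphernalia,nuisance,literature,public_space,binary
food_garbage,nuisance,literature,public_space,binary
dog_waste,nuisance,literature,public_space,binary
discarded_furniture_public,nuisance,literature,public_space,binary
discarded_appliances_public,nuisance,literature,public_space,binary
discarded_tires_public,nuisance,literature,public_space,binary
condoms,nuisance,literature,public_space,binary
cigarette_butts,nuisance,literature,public_space,binary
alcohol_container,nuisance,literature,public_space,binary
clothes,nuisance,literature,public_space,binary
high_weeds_public,nuisance,literature,public_space,binary
broken_glass_public,nuisance,literature,public_space,binary
graffiti_public,nuisance,literature,public_space,binary
shopping_carts,nuisance,community,public_space,binary
tree_debris,nuisance,community,public_space,binary
large_trash,nuisance,community,public_space,binary
batteries,nuisance,community,public_space,binary
fallen_wire,nuisance,community,public_space,binary
broken_water_meter_cover,nuisance,community,public_space,binary
uncovered_storm_drain,nuisance,community,public_space,binary
baby_diapers,nuisance,community,public_space,binary
construction_debris,nuisance,community,public_space,binary
deep_holes,nuisance,community,public_space,binary
standing_water_public,nuisance,community,public_space,binary
other_nuisance_public,nuisance,project_leaders,public_space,text
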