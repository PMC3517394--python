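MAPLE
OAK
PINE
ELM
CEDAR
BIRCH
WALNUT
CHESTNUT
SPRUCE
WILLOW
JUNIPER
MAGNOLIA
DOGWOOD
SYCAMORE
HICKORY
POPLAR
LAUREL
HOLLY
ASPEN
ALDER
HAWTHORN
MULBERRY
PERSIMMON
SASSAFRAS
CATALPA
TULIP
REDBUD
SUMMIT
RIDGE
VALLEY
MEADOW
BROOK
RIVER
LAKE
HILLCREST
FAIRVIEW
SUNSET
SUNRISE
ORCHARD
GARDEN
PARK
GROVE
GLEN
DALE
CRESTWOOD
WOODLAND
FOREST
PRAIRIE
HARBOR
BEACON
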