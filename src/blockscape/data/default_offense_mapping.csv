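label,category
HOMICIDE,violent
MURDER,violent
ASSAULT,violent
AGGRAVATED ASSAULT,violent
SIMPLE ASSAULT,violent
ROBBERY,violent
ARMED ROBBERY,violent
RAPE,violent
SEXUAL ASSAULT,violent
KIDNAPPING,violent
WEAPONS VIOLATION,violent
BURGLARY,property
BREAKING AND ENTERING,property
ARSON,property
VANDALISM,property
CRIMINAL MISCHIEF,property
PROPERTY DAMAGE,property
TRESPASSING,property
DRUG POSSESSION,vice
DRUG SALE,vice
NARCOTICS,vice
PROSTITUTION,vice
GAMBLING,vice
LIQUOR LAW VIOLATION,vice
DISORDERLY CONDUCT,vice
LARCENY,theft
THEFT,theft
SHOPLIFTING,theft
PICKPOCKETING,theft
FRAUD,theft
EMBEZZLEMENT,theft
STOLEN PROPERTY,theft
MOTOR VEHICLE THEFT,vehicular
AUTO THEFT,vehicular
CARJACKING,vehicular
HIT AND RUN,vehicular
DWI,vehicular
RECKLESS DRIVING,vehicular
THEFT FROM VEHICLE,vehicular
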